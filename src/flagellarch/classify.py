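"""Flagellin vs FlgL-like classification, size classes, insert measurement.

Flagellins and the hook-filament junction protein FlgL share an N-terminal
helical block, so a single-model search cannot separate them.  The voting
scheme scores every sequence under both family models and classifies by
the bit-score margin, with an ambiguity band for sequences the two models
cannot distinguish.

Size classes follow the field's thresholds: canonical (<= 800 aa), large
(> 800 aa), giant (> 1,000 aa); the canonical anchor is the 495-aa
Salmonella FliC.  The central insert of a flagellin is delimited per
sequence by locating its conserved N- and C-terminal core domains with
dedicated core models — the insert is whatever lies between them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hmm import ProfileHMM, forward_score, viterbi_decode
from .seqio import SequenceRecord

GIANT_THRESHOLD = 1000
LARGE_THRESHOLD = 800

#: default ambiguity band (bits) for the family margin rule
DEFAULT_BAND = 2.0

#: a core hit below this many bits counts as missing
MIN_CORE_BITS = 10.0


@dataclass
class FamilyCall:
    seq_id: str
    label: str                 # flagellin | flgL_like | ambiguous
    score_flagellin: float
    score_flgl: float

    @property
    def margin(self) -> float:
        return self.score_flagellin - self.score_flgl


@dataclass(frozen=True)
class SizeClass:
    label: str
    length: int


@dataclass
class InsertMeasurement:
    """Central-insert interval of one flagellin, or a structured no-call."""

    seq_id: str
    interval: tuple[int, int] | None
    status: str                # ok | no_call
    reason: str = ""

    @property
    def length(self) -> int | None:
        return None if self.interval is None else self.interval[1] - self.interval[0]


def classify(records: list[SequenceRecord], flagellin_hmm: ProfileHMM,
             flgl_hmm: ProfileHMM,
             ambiguity_band: float = DEFAULT_BAND) -> list[FamilyCall]:
    """Dual-model voting: flagellin if the flagellin-vs-FlgL bit margin
    exceeds +band, FlgL-like below -band, ambiguous inside the band."""
    calls = []
    for rec in records:
        sf = forward_score(flagellin_hmm, rec)
        sg = forward_score(flgl_hmm, rec)
        margin = sf - sg
        if margin > ambiguity_band:
            label = "flagellin"
        elif margin < -ambiguity_band:
            label = "flgL_like"
        else:
            label = "ambiguous"
        calls.append(FamilyCall(rec.id, label, sf, sg))
    return calls


def size_class(record: SequenceRecord) -> SizeClass:
    """Strict-threshold size class: giant > 1,000 aa, large > 800 aa."""
    n = len(record)
    if n > GIANT_THRESHOLD:
        label = "giant"
    elif n > LARGE_THRESHOLD:
        label = "large"
    else:
        label = "canonical"
    return SizeClass(label=label, length=n)


def measure_insert(record: SequenceRecord, ncore_hmm: ProfileHMM,
                   ccore_hmm: ProfileHMM,
                   min_bits: float = MIN_CORE_BITS) -> InsertMeasurement:
    """Delimit the central insert as [end of N-core hit, start of C-core hit).

    A missing core hit yields a no-call with the reason; cores that overlap
    or appear out of order are an error (the sequence violates flagellin
    architecture assumptions and must not be silently measured).
    """
    _, n_hit = viterbi_decode(ncore_hmm, record)
    _, c_hit = viterbi_decode(ccore_hmm, record)
    if n_hit.bit_score < min_bits:
        return InsertMeasurement(record.id, None, "no_call", "missing N-core hit")
    if c_hit.bit_score < min_bits:
        return InsertMeasurement(record.id, None, "no_call", "missing C-core hit")
    if c_hit.start < n_hit.end:
        raise ValueError(
            f"{record.id}: core hits overlap or are out of order "
            f"(N-core {n_hit.interval}, C-core {c_hit.interval})"
        )
    return InsertMeasurement(record.id, (n_hit.end, c_hit.start), "ok")
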