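"""Tandem DE-repeat discovery, DX detection, and architecture assembly.

The Domain-Extension (DE) region is found in two steps mirroring how
internal duplications are discovered in practice: (1) off-diagonal local
self-alignment of each central insert seeds tandem repeat pairs; (2) a
profile HMM built from the pooled tandem copies is scanned over the whole
dataset to pick up singly-occurring DE regions with model-defined
boundaries, the new matches are pooled, and the model rebuilt — iterating
until an iteration adds nothing.

The DX insert is the material strictly between the two tandem DE copies,
and its hallmark is a conserved glycine-rich region detected by a sliding
window scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import SizeClass
from .hmm import DomainHit, ProfileHMM, build_hmm, calibrate_evalues, scan
from .msa import progressive_msa
from .pairwise import LocalAlignmentResult, self_offdiagonal_align
from .scoring import DEFAULT_SCHEME, ScoringScheme
from .seqio import SequenceRecord

#: default minimum repeat-unit length; also the self-alignment exclusion band
MIN_REPEAT_LENGTH = 30

#: DX must be at least this long to be called
MIN_DX_LENGTH = 20


@dataclass
class RepeatPair:
    """Two tandem copies of an internal repeat within one sequence."""

    seq_id: str
    copy1: tuple[int, int]
    copy2: tuple[int, int]
    score: float
    identity: float

    def __post_init__(self) -> None:
        if self.copy1[1] > self.copy2[0]:
            raise ValueError(
                f"{self.seq_id}: repeat copies overlap "
                f"({self.copy1} vs {self.copy2})"
            )


@dataclass
class GlycineRichHit:
    interval: tuple[int, int]
    glycine_fraction: float

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class ArchitectureRejection:
    """Structured refusal to assemble an inconsistent architecture."""

    seq_id: str
    constraint: str


@dataclass
class FlagellinArchitecture:
    """Ordered decomposition of a flagellin: N-core, DE copies, DX, C-core."""

    seq_id: str
    n_core: tuple[int, int]
    de_copies: list[tuple[int, int]]
    dx: tuple[int, int] | None
    c_core: tuple[int, int]
    size: SizeClass

    @property
    def insert_length(self) -> int:
        return self.c_core[0] - self.n_core[1]

    @property
    def architecture_string(self) -> str:
        parts = ["Ncore"]
        for i, _ in enumerate(self.de_copies, start=1):
            parts.append(f"DE{i}")
            if i == 1 and self.dx is not None:
                parts.append("DX")
        parts.append("Ccore")
        return "-".join(parts)


# ---------------------------------------------------------------------------
# tandem repeat seeding


def repeat_score_threshold(residues: str, scheme: ScoringScheme = DEFAULT_SCHEME,
                           exclusion_band: int = MIN_REPEAT_LENGTH,
                           n_shuffles: int = 100, seed: int = 0,
                           quantile: float = 0.99) -> float:
    """Repeat-calling threshold from the shuffled-sequence null.

    The null shuffles the sequence (keeping composition and length,
    destroying repeat structure) and takes the ``ceil(q * (n + 1))``-th
    order statistic of the off-diagonal self-alignment scores — for the
    default 100 shuffles at q = 0.99 this is the null maximum.  Because a
    repeat is only called when its score *strictly exceeds* the threshold,
    exchangeability bounds the false-call probability by 1/(n + 1) for any
    score distribution, ties included.
    """
    rng = np.random.default_rng(seed)
    chars = list(residues)
    scores = np.empty(n_shuffles)
    for t in range(n_shuffles):
        shuffled = "".join(rng.permutation(chars))
        scores[t] = self_offdiagonal_align(shuffled, scheme, exclusion_band).score
    rank = min(int(np.ceil(quantile * (n_shuffles + 1))), n_shuffles)
    return float(np.sort(scores)[rank - 1])


def _alignment_identity(residues: str, res: LocalAlignmentResult) -> float:
    pairs = [
        (q, s) for q, s in res.aligned_columns if q is not None and s is not None
    ]
    if not pairs:
        return 0.0
    same = sum(1 for q, s in pairs if residues[q] == residues[s])
    return same / len(pairs)


def find_tandem_repeats(record: SequenceRecord, insert_interval: tuple[int, int],
                        scheme: ScoringScheme = DEFAULT_SCHEME,
                        min_score: float | None = None,
                        exclusion_band: int = MIN_REPEAT_LENGTH,
                        seed: int = 0, max_pairs: int = 4) -> list[RepeatPair]:
    """Tandem repeat pairs inside the central insert, greedily by score.

    Runs off-diagonal local self-alignment of the insert; every alignment
    scoring at least ``min_score`` (default: the shuffled-insert null's
    99th percentile) yields one pair, whose positions are then masked
    before searching again.  An insert too short to hold two copies
    returns an empty list.
    """
    start, end = insert_interval
    sub = record.residues[start:end]
    if len(sub) < 2 * exclusion_band:
        return []
    if min_score is None:
        min_score = repeat_score_threshold(
            sub, scheme, exclusion_band, seed=seed
        )
    pairs: list[RepeatPair] = []
    mask = np.zeros(len(sub), dtype=bool)
    for _ in range(max_pairs):
        res = self_offdiagonal_align(sub, scheme, exclusion_band,
                                     mask=mask if mask.any() else None)
        # strict inequality: the exchangeability bound on false calls
        # requires that ties with the null threshold are not called
        if res.score <= min_score or not res.aligned_columns:
            break
        a, b = sorted([res.query_interval, res.subject_interval])
        if a[1] > b[0]:
            # long alignment straddling the offset: split at the midpoint
            # of the overlap so the copies stay tandem-ordered
            mid = (a[1] + b[0]) // 2
            a = (a[0], mid)
            b = (mid, b[1])
            if a[1] <= a[0] or b[1] <= b[0]:
                break
        pairs.append(RepeatPair(
            seq_id=record.id,
            copy1=(a[0] + start, a[1] + start),
            copy2=(b[0] + start, b[1] + start),
            score=res.score,
            identity=_alignment_identity(sub, res),
        ))
        mask[a[0]:a[1]] = True
        mask[b[0]:b[1]] = True
    pairs.sort(key=lambda p: p.copy1[0])
    return pairs


# ---------------------------------------------------------------------------
# iterative HMM expansion


@dataclass
class DEInstance:
    """One DE region occurrence pooled into the training set."""

    label: str                  # e.g. "seq/1half", "seq/2half", "seq/ins"
    source_id: str
    interval: tuple[int, int]
    record: SequenceRecord


@dataclass
class DiscoveryResult:
    hmm: ProfileHMM | None
    hits: list[DomainHit]
    instances: list[DEInstance]
    n_iterations: int
    converged: bool


def _instances_from_pairs(records_by_id: dict[str, SequenceRecord],
                          seed_pairs: list[RepeatPair]) -> list[DEInstance]:
    out = []
    pair_no: dict[str, int] = {}
    for pair in seed_pairs:
        rec = records_by_id[pair.seq_id]
        k = pair_no.get(pair.seq_id, 0)
        pair_no[pair.seq_id] = k + 1
        extra = "" if k == 0 else f".{k + 1}"
        for tag, (s, e) in (("1half", pair.copy1), ("2half", pair.copy2)):
            label = f"{pair.seq_id}/{tag}{extra}"
            out.append(DEInstance(label, pair.seq_id, (s, e),
                                  rec.slice(s, e, suffix=f"/{tag}{extra}")))
    return out


def _overlaps(iv: tuple[int, int], existing: list[tuple[int, int]],
              min_frac: float = 0.5) -> bool:
    length = iv[1] - iv[0]
    for s, e in existing:
        shared = min(iv[1], e) - max(iv[0], s)
        if shared > 0 and shared / max(length, 1) >= min_frac:
            return True
    return False


def iterative_de_discovery(records: list[SequenceRecord],
                           seed_pairs: list[RepeatPair],
                           evalue_threshold: float = 0.1,
                           max_iter: int = 5,
                           seed: int = 0) -> DiscoveryResult:
    """Expand the tandem-seeded DE set by iterative HMM search.

    Each round aligns the current DE instances, builds and calibrates a
    profile HMM, scans every record, and pools novel non-overlapping hits.
    Convergence requires a *confirming* round: it is declared when a round
    after the first adds nothing, so even a dataset whose tandem seeds
    already cover every copy runs (and reports) the round that found
    nothing new.  Hitting ``max_iter`` without convergence is flagged in
    the result, not raised.  The instance set grows monotonically.
    """
    if not seed_pairs:
        raise ValueError("iterative discovery needs at least one seed pair")
    records_by_id = {r.id: r for r in records}
    instances = _instances_from_pairs(records_by_id, seed_pairs)
    hmm: ProfileHMM | None = None
    hits: list[DomainHit] = []
    converged = False
    n_iter = 0
    while n_iter < max_iter:
        n_iter += 1
        msa = progressive_msa([inst.record for inst in instances])
        hmm = build_hmm(msa, name=f"DE_iter{n_iter}")
        calibrate_evalues(hmm, records, n_shuffles=100, seed=seed + 1)
        hits = scan(hmm, records, evalue_threshold=evalue_threshold)
        known: dict[str, list[tuple[int, int]]] = {}
        for inst in instances:
            known.setdefault(inst.source_id, []).append(inst.interval)
        novel = [
            h for h in hits
            if not _overlaps(h.interval, known.get(h.seq_id, []))
        ]
        if not novel and n_iter >= 2:
            converged = True
            break
        taken = {i.label for i in instances}
        for h in novel:
            label = f"{h.seq_id}/ins"
            k = 2
            while label in taken:
                label = f"{h.seq_id}/ins{k}"
                k += 1
            taken.add(label)
            suffix = label[len(h.seq_id):]
            instances.append(DEInstance(
                label, h.seq_id, h.interval,
                records_by_id[h.seq_id].slice(h.start, h.end, suffix=suffix),
            ))
    return DiscoveryResult(hmm=hmm, hits=hits, instances=instances,
                           n_iterations=n_iter, converged=converged)


# ---------------------------------------------------------------------------
# DX and the glycine-rich region


def detect_dx(record: SequenceRecord, de_copies: list[tuple[int, int]],
              min_dx_length: int = MIN_DX_LENGTH) -> tuple[int, int] | None:
    """The DX insert: material strictly between exactly two tandem DE
    copies, if long enough.  Any other copy count yields no DX by contract."""
    if len(de_copies) != 2:
        return None
    (s1, e1), (s2, e2) = sorted(de_copies)
    if e1 > s2:
        raise ValueError(f"{record.id}: DE copies overlap")
    if s2 - e1 < min_dx_length:
        return None
    return (e1, s2)


def glycine_rich_scan(record: SequenceRecord, dx_interval: tuple[int, int],
                      window: int = 11, min_fraction: float = 0.4,
                      min_length: int = 20) -> list[GlycineRichHit]:
    """Glycine-rich stretches inside the DX insert.

    Slides an odd window across DX, marks windows whose glycine fraction
    reaches ``min_fraction``, merges overlapping marked spans, and reports
    merged intervals of at least ``min_length`` with their overall
    fraction.
    """
    if window < 5:
        raise ValueError("window must be >= 5")
    s, e = dx_interval
    sub = record.residues[s:e]
    if len(sub) < window:
        return []
    is_g = np.frombuffer(sub.encode(), dtype="S1") == b"G"
    counts = np.convolve(is_g.astype(int), np.ones(window, dtype=int), "valid")
    marked = np.nonzero(counts / window >= min_fraction)[0]
    # merge the spans covered by marked windows wherever they overlap
    merged: list[list[int]] = []
    for i in marked:
        lo, hi = int(i), int(i) + window
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    hits: list[GlycineRichHit] = []
    for lo, hi in merged:
        if hi - lo >= min_length:
            frac = float(is_g[lo:hi].mean())
            hits.append(GlycineRichHit((lo + s, hi + s), frac))
    return hits


# ---------------------------------------------------------------------------
# architecture assembly


def assemble_architecture(record: SequenceRecord,
                          n_core: tuple[int, int], c_core: tuple[int, int],
                          de_hits: list[tuple[int, int]],
                          dx: tuple[int, int] | None,
                          size: SizeClass):
    """Compose per-sequence components into an ordered architecture.

    Overlapping or out-of-order components yield an
    :class:`ArchitectureRejection` naming the first violated constraint —
    never a silently trimmed architecture.
    """
    de = sorted(de_hits)
    components = [("n_core", n_core)] + [
        (f"de{i + 1}", iv) for i, iv in enumerate(de)
    ] + [("c_core", c_core)]
    if dx is not None:
        if len(de) != 2:
            return ArchitectureRejection(record.id, "dx_requires_two_de_copies")
        if not (de[0][1] <= dx[0] and dx[1] <= de[1][0]):
            return ArchitectureRejection(record.id, "dx_not_between_de_copies")
        components.insert(2, ("dx", dx))
        components.sort(key=lambda c: c[1][0])
    prev_name, prev_iv = components[0]
    for name, iv in components[1:]:
        if iv[0] < prev_iv[1]:
            return ArchitectureRejection(record.id, f"overlap:{prev_name}/{name}")
        prev_name, prev_iv = name, iv
    last = components[-1][1][1]
    if components[0][1][0] < 0 or last > len(record):
        return ArchitectureRejection(record.id, "interval_out_of_bounds")
    return FlagellinArchitecture(
        seq_id=record.id, n_core=n_core, de_copies=de, dx=dx,
        c_core=c_core, size=size,
    )
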