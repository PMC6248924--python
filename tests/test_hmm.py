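import numpy as np
import pytest

from flagellarch.hmm import (ProfileHMM, build_hmm,
                             calibrate_evalues, forward_score, scan,
                             viterbi_decode)
from flagellarch.seqio import MultipleAlignment, SequenceRecord

from conftest import random_peptide
from oracles import core_transition_mass, enumerate_hmm_paths


def _consensus(msa: MultipleAlignment) -> str:
    out = []
    for j in range(msa.length):
        col = [c for c in msa.column(j) if c != "-"]
        if len(col) * 2 >= msa.n_rows:
            out.append(max(set(col), key=col.count))
    return "".join(out)


@pytest.fixture(scope="module")
def toy_hmm():
    msa = MultipleAlignment([
        ("a", "MKD"),
        ("b", "MKD"),
        ("c", "MRD"),
        ("d", "M-D"),
    ])
    return build_hmm(msa, name="toy")


class TestBuild:
    def test_identical_rows_give_concentrated_emissions(self):
        msa = MultipleAlignment([(f"s{i}", "MKVLA") for i in range(4)])
        h = build_hmm(msa)
        assert h.length == 5
        for k, ch in enumerate("MKVLA", start=1):
            row = h.match_em[k]
            from flagellarch.scoring import RESIDUE_INDEX
            assert row.argmax() == RESIDUE_INDEX[ch]

    def test_distributions_normalised_for_random_msas(self, rng):
        for _ in range(3):
            rows = []
            base = random_peptide(rng, 12)
            for i in range(5):
                chars = list(base)
                for j in range(len(chars)):
                    if rng.random() < 0.2:
                        chars[j] = random_peptide(rng, 1)
                    if rng.random() < 0.1:
                        chars[j] = "-"
                rows.append((f"s{i}", "".join(chars)))
            h = build_hmm(MultipleAlignment(rows))
            h.validate()  # raises if any row is off by > 1e-9

    def test_no_qualifying_match_column_rejected(self):
        msa = MultipleAlignment([("a", "M--"), ("b", "K--"), ("c", "-V-")])
        with pytest.raises(ValueError, match="match state"):
            build_hmm(msa, match_column_rule=0.2)

    def test_consensus_beats_shuffles(self, rng):
        rows = [(f"s{i}", "MKVLATGDEWHRPC") for i in range(5)]
        h = build_hmm(MultipleAlignment(rows))
        cons = "MKVLATGDEWHRPC"
        ref = forward_score(h, cons)
        chars = list(cons)
        better = sum(
            1 for _ in range(100)
            if forward_score(h, "".join(rng.permutation(chars))) >= ref
        )
        assert better <= 1


class TestScoringOracle:
    """Forward and Viterbi against explicit enumeration of all state paths."""

    @pytest.mark.parametrize("seq", ["MKD", "MD", "MKKD", "WWW", "M", "KDKD"])
    def test_forward_matches_enumeration(self, toy_hmm, seq):
        fwd_enum, _ = enumerate_hmm_paths(toy_hmm, seq)
        assert forward_score(toy_hmm, seq) == pytest.approx(fwd_enum, abs=1e-6)

    @pytest.mark.parametrize("seq", ["MKD", "MD", "MKKD", "WWW", "KDKD"])
    def test_viterbi_matches_enumeration(self, toy_hmm, seq):
        _, vit_enum = enumerate_hmm_paths(toy_hmm, seq)
        _, hit = viterbi_decode(toy_hmm, seq)
        assert hit.bit_score == pytest.approx(vit_enum, abs=1e-6)

    def test_viterbi_never_exceeds_forward(self, toy_hmm, rng):
        for _ in range(20):
            s = random_peptide(rng, int(rng.integers(1, 8)))
            _, hit = viterbi_decode(toy_hmm, s)
            assert hit.bit_score <= forward_score(toy_hmm, s) + 1e-9

    def test_score_ignores_id_and_description(self, toy_hmm):
        a = forward_score(toy_hmm, SequenceRecord("x", "MKD", "one thing"))
        b = forward_score(toy_hmm, SequenceRecord("y", "MKD", "another"))
        assert a == b

    def test_probability_conservation_over_short_sequences(self, toy_hmm):
        """Summing P(s) x background over all sequences of length <= 2
        equals the model's transition-path mass for windows of those
        lengths placed anywhere in the sequence."""
        from flagellarch.seqio import AMINO_ACIDS

        bg = toy_hmm.background
        for n in (1, 2):
            total = 0.0
            seqs = (
                list(AMINO_ACIDS) if n == 1
                else [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
            )
            for s in seqs:
                bits = forward_score(toy_hmm, s)
                p_bg = np.prod([bg[AMINO_ACIDS.index(c)] for c in s])
                total += (2.0 ** bits) * p_bg
            expected = sum(
                (n - ell + 1) * core_transition_mass(toy_hmm, ell)
                for ell in range(1, n + 1)
            )
            assert total == pytest.approx(expected, abs=1e-6)


class TestViterbiEnvelope:
    def test_consensus_hit_spans_full_sequence(self, rng):
        rows = [(f"s{i}", "MKVLATGDEWHRPC") for i in range(5)]
        h = build_hmm(MultipleAlignment(rows))
        _, hit = viterbi_decode(h, "MKVLATGDEWHRPC")
        assert (hit.start, hit.end) == (0, 14)

    def test_embedded_domain_is_localised(self, rng):
        rows = [(f"s{i}", "MKVLATGDEWHRPC") for i in range(5)]
        h = build_hmm(MultipleAlignment(rows))
        left = random_peptide(rng, 30)
        right = random_peptide(rng, 30)
        _, hit = viterbi_decode(h, left + "MKVLATGDEWHRPC" + right)
        assert hit.start >= 25 and hit.end <= 75
        assert hit.end - hit.start >= 10

    def test_random_sequences_are_insignificant(self, rng):
        """Unrelated random sequences fall below the significance
        threshold (E-value 0.1) under a calibrated model: local-alignment
        bit maxima on random sequences sit near zero by construction, so
        significance — not the sign of the bit score — is the null test."""
        rows = [(f"s{i}", "MKVLATGDEWHRPC") for i in range(5)]
        h = build_hmm(MultipleAlignment(rows))
        db = [SequenceRecord(f"bg{i}", random_peptide(rng, 50))
              for i in range(10)]
        calibrate_evalues(h, db, seed=2)
        insignificant = sum(
            1 for _ in range(100)
            if h.calibration.evalue(
                forward_score(h, random_peptide(rng, 50))) > 0.1
        )
        assert insignificant >= 95


@pytest.fixture(scope="module")
def family():
    rng = np.random.default_rng(5)
    base = "".join(
        "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(20, size=40)
    )
    rows = []
    for i in range(6):
        chars = list(base)
        for j in range(len(chars)):
            if rng.random() < 0.15:
                chars[j] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
        rows.append((f"s{i}", "".join(chars)))
    h = build_hmm(MultipleAlignment(rows), name="fam")
    db = [
        SequenceRecord(f"db{i}", "".join(
            "ACDEFGHIKLMNPQRSTVWY"[k] for k in rng.integers(20, size=120)))
        for i in range(10)
    ]
    return h, db


class TestCalibration:
    def test_median_shuffle_maps_to_half_database(self, family):
        h, db = family
        cal = calibrate_evalues(h, db, n_shuffles=150, seed=3)
        rng = np.random.default_rng(9)
        meds = []
        for rec in db:
            s = "".join(rng.permutation(list(rec.residues)))
            meds.append(forward_score(h, s))
        ev = cal.evalue(float(np.median(meds)))
        assert cal.n_db / 2 / 1.5 <= ev <= cal.n_db / 2 * 1.5

    def test_evalue_monotone_decreasing_in_bits(self, family):
        h, db = family
        cal = calibrate_evalues(h, db, seed=3)
        xs = np.linspace(-20, 60, 30)
        es = [cal.evalue(x) for x in xs]
        assert all(a >= b for a, b in zip(es, es[1:]))

    def test_same_seed_reproduces_calibration(self, family):
        h, db = family
        c1 = calibrate_evalues(h, db, seed=11)
        c2 = calibrate_evalues(h, db, seed=11)
        assert (c1.loc, c1.scale, c1.n_db) == (c2.loc, c2.scale, c2.n_db)

    def test_too_few_shuffles_rejected(self, family):
        h, db = family
        with pytest.raises(ValueError):
            calibrate_evalues(h, db, n_shuffles=10)


@pytest.fixture(scope="module")
def domain_model():
    rng = np.random.default_rng(21)
    unit = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(20, size=35))
    rows = []
    for i in range(6):
        chars = list(unit)
        for j in range(len(chars)):
            if rng.random() < 0.1:
                chars[j] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
        rows.append((f"u{i}", "".join(chars)))
    h = build_hmm(MultipleAlignment(rows), name="unit")
    return h, unit


class TestScan:
    def test_two_planted_copies_found(self, domain_model, rng):
        h, unit = domain_model
        flank = random_peptide(rng, 40)
        rec = SequenceRecord("two", flank + unit + random_peptide(rng, 30)
                             + unit + flank)
        db = [rec] + [SequenceRecord(f"bg{i}", random_peptide(rng, 150))
                      for i in range(5)]
        calibrate_evalues(h, db, seed=4)
        hits = [x for x in scan(h, db, 0.1) if x.seq_id == "two"]
        assert len(hits) == 2
        planted = [(40, 75), (105, 140)]
        for hit, (ps, pe) in zip(hits, planted):
            overlap = min(hit.end, pe) - max(hit.start, ps)
            assert overlap >= 0.8 * (pe - ps)
        assert hits[0].end <= hits[1].start

    def test_background_rarely_hits(self, domain_model):
        h, _ = domain_model
        rng = np.random.default_rng(31)
        db = [SequenceRecord(f"bg{i}", random_peptide(rng, 150))
              for i in range(10)]
        calibrate_evalues(h, db, seed=6)
        n_with_hits = 0
        for t in range(100):
            rec = SequenceRecord("q", random_peptide(rng, 150))
            if scan(h, [rec], 0.1):
                n_with_hits += 1
        assert n_with_hits <= 5

    def test_hits_within_bounds_and_disjoint(self, domain_model, rng):
        h, unit = domain_model
        rec = SequenceRecord(
            "multi", (unit + random_peptide(rng, 10)) * 3
        )
        db = [rec] + [SequenceRecord(f"bg{i}", random_peptide(rng, 120))
                      for i in range(5)]
        calibrate_evalues(h, db, seed=8)
        hits = [x for x in scan(h, db, 0.1) if x.seq_id == "multi"]
        prev_end = 0
        for hit in hits:
            assert 0 <= hit.start < hit.end <= len(rec)
            assert hit.start >= prev_end
            prev_end = hit.end

    def test_uncalibrated_scan_rejected(self, domain_model):
        h, _ = domain_model
        h2 = ProfileHMM(**{f.name: getattr(h, f.name)
                           for f in h.__dataclass_fields__.values()
                           if f.name != "calibration"})
        with pytest.raises(ValueError):
            scan(h2, [SequenceRecord("a", "MKVLAT")], 0.1)


class TestSerialization:
    def test_round_trip(self, toy_hmm, tmp_path):
        p = tmp_path / "m.hmm"
        toy_hmm.save(p)
        back = ProfileHMM.load(p)
        assert back.length == toy_hmm.length
        assert np.allclose(back.match_em, toy_hmm.match_em, atol=1e-7)
        assert np.allclose(back.t_mm, toy_hmm.t_mm, atol=1e-7)
        s = "MKDWKD"
        assert forward_score(back, s) == pytest.approx(
            forward_score(toy_hmm, s), abs=1e-5)
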