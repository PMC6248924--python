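import numpy as np
import pytest

from flagellarch.classify import SizeClass
from flagellarch.repeats import (ArchitectureRejection, FlagellinArchitecture,
                                 RepeatPair, assemble_architecture, detect_dx,
                                 find_tandem_repeats, glycine_rich_scan,
                                 iterative_de_discovery)
from flagellarch.seqio import SequenceRecord
from flagellarch.simulate import oceanospirillales_preset, generate

from conftest import random_peptide


def _planted_record(rng, unit_len=60, gap_len=20):
    left = random_peptide(rng, 60)
    unit = random_peptide(rng, unit_len)
    mid = random_peptide(rng, gap_len)
    right = random_peptide(rng, 60)
    s = left + unit + mid + unit + right
    copy1 = (60, 60 + unit_len)
    copy2 = (60 + unit_len + gap_len, 60 + 2 * unit_len + gap_len)
    return SequenceRecord("planted", s), copy1, copy2


class TestTandemSeeding:
    def test_planted_exact_duplication_recovered(self, scheme, rng):
        rec, c1, c2 = _planted_record(rng)
        insert = (10, len(rec) - 10)
        pairs = find_tandem_repeats(rec, insert, scheme, seed=3)
        assert len(pairs) == 1
        p = pairs[0]
        for got, want in ((p.copy1, c1), (p.copy2, c2)):
            assert abs(got[0] - want[0]) <= 3
            assert abs(got[1] - want[1]) <= 3
        assert p.identity > 0.95

    def test_random_insert_rarely_yields_pairs(self, scheme):
        rng = np.random.default_rng(55)
        n_called = 0
        for t in range(100):
            rec = SequenceRecord("r", random_peptide(rng, 200))
            if find_tandem_repeats(rec, (0, 200), scheme, seed=t):
                n_called += 1
        assert n_called <= 5

    def test_insert_too_short_returns_empty(self, scheme, rng):
        rec = SequenceRecord("r", random_peptide(rng, 100))
        assert find_tandem_repeats(rec, (20, 50), scheme, seed=1) == []

    def test_copies_respect_tandem_order(self, scheme, rng):
        rec, _, _ = _planted_record(rng, unit_len=80, gap_len=0)
        pairs = find_tandem_repeats(rec, (0, len(rec)), scheme, seed=2)
        for p in pairs:
            assert p.copy1[1] <= p.copy2[0]

    def test_overlapping_pair_construction_rejected(self):
        with pytest.raises(ValueError):
            RepeatPair("x", (10, 40), (30, 60), 100.0, 0.9)


@pytest.fixture(scope="module")
def dataset():
    """4 tandem + 2 single-copy + 2 plain flagellins, known truth."""
    cfg = oceanospirillales_preset(17)
    records, truth = generate(cfg)
    return cfg, records, truth


class TestIterativeDiscovery:
    def _seed_pairs(self, records, truth, scheme):
        pairs = []
        for rec in records:
            t = truth.leaves[rec.id]
            if t.model == "tandem_DE_plus_DX":
                iv = t.insert
                pairs.extend(find_tandem_repeats(rec, iv, scheme, seed=7))
        return pairs

    def test_all_planted_copies_found(self, dataset, scheme):
        cfg, records, truth = dataset
        seed_pairs = self._seed_pairs(records, truth, scheme)
        assert len(seed_pairs) == 4
        res = iterative_de_discovery(records, seed_pairs, seed=11)
        assert res.converged
        assert res.n_iterations <= 3
        n_truth = sum(len(t.de_copies) for t in truth.leaves.values())
        assert n_truth == 10
        found = {(h.seq_id, h.start, h.end) for h in res.hits}
        n_matched = 0
        for sid, t in truth.leaves.items():
            for ts, te in t.de_copies:
                for hs, he in [(s, e) for s2, s, e in
                               ((x, y, z) for x, y, z in found) if s2 == sid]:
                    if min(te, he) - max(ts, hs) >= 0.8 * (te - ts):
                        n_matched += 1
                        break
        assert n_matched == n_truth

    def test_tandem_only_dataset_converges_in_two_iterations(self, scheme):
        cfg = oceanospirillales_preset(23)
        cfg = type(cfg)(**{**cfg.__dict__,
                           "leaf_models": ("tandem_DE",) * cfg.n_taxa})
        records, truth = generate(cfg)
        pairs = []
        for rec in records:
            t = truth.leaves[rec.id]
            pairs.extend(find_tandem_repeats(rec, t.insert, scheme, seed=5))
        res = iterative_de_discovery(records, pairs, seed=13)
        assert res.converged
        assert res.n_iterations == 2  # second pass finds nothing new

    def test_instance_set_grows_monotonically(self, dataset, scheme):
        cfg, records, truth = dataset
        seed_pairs = self._seed_pairs(records, truth, scheme)
        res = iterative_de_discovery(records, seed_pairs, seed=11)
        assert len(res.instances) >= 2 * len(seed_pairs)

    def test_empty_seed_pairs_rejected(self, dataset):
        _, records, _ = dataset
        with pytest.raises(ValueError):
            iterative_de_discovery(records, [], seed=1)


class TestDX:
    def test_two_copies_with_gap_give_dx(self, rng):
        rec = SequenceRecord("r", random_peptide(rng, 500))
        dx = detect_dx(rec, [(50, 150), (270, 370)])
        assert dx == (150, 270)

    def test_abutting_copies_give_no_dx(self, rng):
        rec = SequenceRecord("r", random_peptide(rng, 400))
        assert detect_dx(rec, [(50, 150), (150, 250)]) is None

    def test_short_gap_below_minimum_gives_no_dx(self, rng):
        rec = SequenceRecord("r", random_peptide(rng, 400))
        assert detect_dx(rec, [(50, 150), (160, 260)]) is None

    @pytest.mark.parametrize("copies", [[], [(50, 150)],
                                        [(0, 50), (60, 110), (150, 200)]])
    def test_copy_count_other_than_two_gives_no_dx(self, rng, copies):
        rec = SequenceRecord("r", random_peptide(rng, 400))
        assert detect_dx(rec, copies) is None

    def test_planted_dx_recovered_from_truth(self):
        cfg = oceanospirillales_preset(29)
        records, truth = generate(cfg)
        for rec in records:
            t = truth.leaves[rec.id]
            if t.model != "tandem_DE_plus_DX":
                continue
            dx = detect_dx(rec, t.de_copies)
            assert dx is not None
            assert abs(dx[0] - t.dx[0]) <= 3
            assert abs(dx[1] - t.dx[1]) <= 3


class TestGlycineScan:
    def test_poly_g_block_saturates(self, rng):
        pre = random_peptide(rng, 40).replace("G", "A")
        post = random_peptide(rng, 40).replace("G", "A")
        rec = SequenceRecord("r", pre + "G" * 35 + post)
        hits = glycine_rich_scan(rec, (0, len(rec)), window=11,
                                 min_fraction=0.4)
        assert len(hits) == 1
        assert hits[0].length >= 35
        s, e = hits[0].interval
        assert rec.residues[s + 5:e - 5].count("G") >= 30

    def test_background_glycine_rarely_hits(self):
        rng = np.random.default_rng(91)
        aa = "ACDEFHIKLMNPQRSTVWY"  # glycine via explicit 7% chance
        n_with_hit = 0
        for t in range(100):
            chars = [
                "G" if rng.random() < 0.07 else aa[rng.integers(len(aa))]
                for _ in range(120)
            ]
            rec = SequenceRecord("r", "".join(chars))
            if glycine_rich_scan(rec, (0, 120), 11, 0.4, 20):
                n_with_hit += 1
        assert n_with_hit <= 1

    def test_hits_stay_within_dx(self, rng):
        rec = SequenceRecord("r", "G" * 200)
        hits = glycine_rich_scan(rec, (60, 140), 11, 0.4, 20)
        for h in hits:
            assert 60 <= h.interval[0] < h.interval[1] <= 140

    def test_small_window_rejected(self, rng):
        rec = SequenceRecord("r", random_peptide(rng, 50))
        with pytest.raises(ValueError):
            glycine_rich_scan(rec, (0, 50), window=3)


class TestArchitecture:
    def test_canonical_flagellin_has_no_de_no_dx(self, rng):
        rec = SequenceRecord("r", random_peptide(rng, 495))
        arch = assemble_architecture(rec, (0, 180), (330, 495), [], None,
                                     SizeClass("canonical", 495))
        assert isinstance(arch, FlagellinArchitecture)
        assert arch.architecture_string == "Ncore-Ccore"
        assert arch.insert_length == 150

    def test_giant_architecture_string(self, rng):
        rec = SequenceRecord("r", random_peptide(rng, 1020))
        arch = assemble_architecture(
            rec, (0, 180), (840, 1020), [(180, 440), (580, 840)],
            (440, 580), SizeClass("giant", 1020))
        assert isinstance(arch, FlagellinArchitecture)
        assert arch.architecture_string == "Ncore-DE1-DX-DE2-Ccore"

    def test_overlapping_de_hits_rejected_not_trimmed(self, rng):
        rec = SequenceRecord("r", random_peptide(rng, 600))
        arch = assemble_architecture(
            rec, (0, 100), (500, 600), [(100, 300), (250, 450)], None,
            SizeClass("canonical", 600))
        assert isinstance(arch, ArchitectureRejection)
        assert "overlap" in arch.constraint

    def test_dx_outside_copies_rejected(self, rng):
        rec = SequenceRecord("r", random_peptide(rng, 600))
        arch = assemble_architecture(
            rec, (0, 100), (500, 600), [(100, 200), (300, 400)],
            (350, 450), SizeClass("canonical", 600))
        assert isinstance(arch, ArchitectureRejection)
        assert arch.constraint == "dx_not_between_de_copies"
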