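import numpy as np
import pytest

from flagellarch.pairwise import (dotplot, global_align, local_align,
                                  self_offdiagonal_align)
from conftest import random_peptide
from oracles import brute_global_score, brute_local_score

REDUCED = "ACDE"  # 4-letter alphabet for exhaustive enumeration


def _rand(rng, n):
    return "".join(REDUCED[i] for i in rng.integers(len(REDUCED), size=n))


class TestLocal:
    def test_identical_sequences_full_diagonal(self, scheme):
        s = "MKVLATGDEW"
        res = local_align(s, s, scheme)
        expected = sum(scheme.score(c, c) for c in s)
        assert res.score == expected
        assert res.query_interval == (0, len(s))
        assert res.subject_interval == (0, len(s))

    def test_no_positive_pair_scores_zero(self, simple_scheme):
        res = local_align("AAAA", "CCCC", simple_scheme)
        assert res.score == 0
        assert res.query_interval == (0, 0)
        assert res.aligned_columns == []

    def test_empty_sequence_rejected(self, scheme):
        with pytest.raises(ValueError):
            local_align("", "MKV", scheme)

    @pytest.mark.parametrize("la,lb", [(3, 3), (4, 5), (6, 6), (5, 6)])
    def test_matches_pure_enumeration(self, simple_scheme, rng, la, lb):
        """DP local score equals exhaustive enumeration over every gapped
        local alignment of every substring pair."""
        for _ in range(4):
            a, b = _rand(rng, la), _rand(rng, lb)
            got = local_align(a, b, simple_scheme).score
            assert got == brute_local_score(a, b, simple_scheme)

    def test_score_symmetry(self, scheme, rng):
        for _ in range(5):
            a = random_peptide(rng, 12)
            b = random_peptide(rng, 15)
            assert local_align(a, b, scheme).score == local_align(b, a, scheme).score

    def test_score_recomputes_from_columns(self, scheme, rng):
        a, b = random_peptide(rng, 25), random_peptide(rng, 25)
        res = local_align(a, b, scheme)
        total, gap_q, gap_s = 0, 0, 0
        run_q = run_s = False
        for q, s in res.aligned_columns:
            if q is not None and s is not None:
                total += scheme.score(a[q], b[s])
                run_q = run_s = False
            elif q is None:
                total -= scheme.gap_extend if run_q else scheme.gap_open
                run_q, run_s = True, False
            else:
                total -= scheme.gap_extend if run_s else scheme.gap_open
                run_s, run_q = True, False
        assert total == res.score

    def test_monotone_under_extension(self, scheme, rng):
        a = random_peptide(rng, 20)
        b = random_peptide(rng, 20)
        base = local_align(a, b, scheme).score
        assert local_align(a + "W", b, scheme).score >= base
        assert local_align(a, b + "W", scheme).score >= base


class TestGlobal:
    def test_identity_no_gaps(self, scheme):
        res = global_align("AC", "AC", scheme)
        assert res.score == scheme.score("A", "A") + scheme.score("C", "C")
        assert res.aligned_columns == [(0, 0), (1, 1)]

    def test_empty_input_rejected(self, scheme):
        with pytest.raises(ValueError):
            global_align("MKV", "", scheme)

    @pytest.mark.parametrize("la,lb", [(4, 4), (5, 6), (7, 7), (6, 5)])
    def test_matches_pure_enumeration(self, simple_scheme, rng, la, lb):
        for _ in range(4):
            a, b = _rand(rng, la), _rand(rng, lb)
            got = global_align(a, b, simple_scheme).score
            assert got == brute_global_score(a, b, simple_scheme)


class TestDotPlot:
    def test_self_plot_symmetric_diagonal_maximal(self, scheme, rng):
        s = random_peptide(rng, 40)
        dp = dotplot(s, s, window=7, scheme=scheme)
        assert np.allclose(dp.matrix, dp.matrix.T)
        assert np.all(np.diag(dp.matrix) >= dp.matrix.max(axis=1) - 1e-9)

    def test_window_one_is_raw_substitution(self, scheme, rng):
        a, b = random_peptide(rng, 10), random_peptide(rng, 12)
        dp = dotplot(a, b, window=1, scheme=scheme)
        for i, ca in enumerate(a):
            for j, cb in enumerate(b):
                assert dp.matrix[i, j] == scheme.score(ca, cb)

    def test_even_window_rejected(self, scheme):
        with pytest.raises(ValueError):
            dotplot("MKVLATGDEW", "MKVLATGDEW", window=4, scheme=scheme)

    def test_planted_repeat_shows_offdiagonal(self, scheme, rng):
        core = random_peptide(rng, 40)
        unit = random_peptide(rng, 30)
        s = core + unit + unit
        dp = dotplot(s, s, window=11, scheme=scheme)
        n = len(s)
        off = np.array([dp.matrix[i, i + 30] for i in range(40, 70)])
        background = np.array([
            dp.matrix[i, j] for i in range(n) for j in range(i + 15, n, 17)
            if not (40 <= i < 70 and j == i + 30)
        ])
        assert off.mean() > background.mean() + 3 * background.std() / np.sqrt(len(background))


class TestProperties:
    """Invariants over arbitrary sequences (hypothesis, derandomised)."""

    from hypothesis import given, settings, strategies as st

    peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1,
                       max_size=12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(a=peptides, b=peptides)
    def test_local_score_symmetric_and_nonnegative(self, a, b):
        from flagellarch.scoring import DEFAULT_SCHEME

        fwd = local_align(a, b, DEFAULT_SCHEME).score
        assert fwd >= 0
        assert fwd == local_align(b, a, DEFAULT_SCHEME).score

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(a=peptides)
    def test_self_alignment_achieves_identity_score(self, a):
        from flagellarch.scoring import DEFAULT_SCHEME

        expected = sum(DEFAULT_SCHEME.score(c, c) for c in a)
        assert local_align(a, a, DEFAULT_SCHEME).score == expected

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(a=peptides, b=peptides)
    def test_global_score_never_exceeds_local(self, a, b):
        from flagellarch.scoring import DEFAULT_SCHEME

        g = global_align(a, b, DEFAULT_SCHEME).score
        l = local_align(a, b, DEFAULT_SCHEME).score
        assert g <= l


class TestSelfOffDiagonal:
    def test_planted_exact_duplicate_recovered(self, scheme, rng):
        left = random_peptide(rng, 50)
        unit = random_peptide(rng, 60)
        mid = random_peptide(rng, 20)
        right = random_peptide(rng, 50)
        s = left + unit + mid + unit + right
        res = self_offdiagonal_align(s, scheme, exclusion_band=30)
        a, b = sorted([res.query_interval, res.subject_interval])
        assert abs(a[0] - 50) <= 0 and abs(a[1] - 110) <= 0
        assert abs(b[0] - 130) <= 0 and abs(b[1] - 190) <= 0

    def test_random_sequence_stays_below_threshold(self, scheme):
        """i.i.d. sequences essentially never reach the repeat-calling
        threshold derived from their own shuffled null."""
        from flagellarch.repeats import repeat_score_threshold

        rng = np.random.default_rng(77)
        n_hits = 0
        for t in range(200):
            s = random_peptide(rng, 100)
            thr = repeat_score_threshold(s, scheme, 20, n_shuffles=100, seed=t)
            if self_offdiagonal_align(s, scheme, 20).score > thr:
                n_hits += 1
        # per-sequence false-call probability is bounded by 1/101 < 0.01
        # (exchangeability); 5 is the 99% binomial envelope at p = 0.01
        assert n_hits <= 5

    def test_band_bounds(self, scheme):
        with pytest.raises(ValueError):
            self_offdiagonal_align("MKVLAT", scheme, exclusion_band=6)
        with pytest.raises(ValueError):
            self_offdiagonal_align("MKVLAT", scheme, exclusion_band=0)
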