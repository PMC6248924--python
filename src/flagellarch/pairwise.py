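"""Affine-gap pairwise alignment and windowed dot-plots.

These are the engines behind repeat inspection (dot-plots of a sequence
against itself), tandem-repeat seeding (off-diagonal self local alignment)
and progressive MSA construction (global profile alignment).  All dynamic
programming runs over a dense pair-score matrix, so the same kernels serve
sequence-sequence and profile-profile alignment.

Coordinates are 0-based half-open throughout.  Tie-breaking is fixed as
diagonal > up > left so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .scoring import ScoringScheme, DEFAULT_SCHEME, encode
from .seqio import SequenceRecord

_NEG = -1e18

# pointer codes
_STOP, _DIAG, _UP, _LEFT = 0, 1, 2, 3


def _residues(x) -> str:
    if isinstance(x, SequenceRecord):
        return x.residues
    if isinstance(x, str):
        if not x:
            raise ValueError("empty sequence")
        return x.upper()
    raise TypeError(f"expected SequenceRecord or str, got {type(x)!r}")


@dataclass
class LocalAlignmentResult:
    """One optimal local alignment: score, intervals, and columns.

    ``aligned_columns`` pairs a query index (or None for a gap) with a
    subject index (or None).  Intervals are 0-based half-open; an empty
    alignment has score 0 and empty intervals.
    """

    score: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    aligned_columns: list[tuple[int | None, int | None]]


@dataclass
class GlobalAlignmentResult:
    score: float
    aligned_columns: list[tuple[int | None, int | None]]


@dataclass
class DotPlot:
    """Windowed self/pair similarity: entry (i, j) is the substitution-score
    sum over the diagonal window centred at (i, j), truncated at the edges."""

    window: int
    matrix: np.ndarray


# ---------------------------------------------------------------------------
# kernels


@njit(cache=True)
def _sw_fill(S, gap_open, gap_extend, band):
    """Smith-Waterman affine fill.  ``band`` > 0 forbids cells |i-j| < band
    (the off-diagonal self-alignment case); 0 disables the constraint."""
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), _NEG)
    F = np.full((n + 1, m + 1), _NEG)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 = extend, 0 = open
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if band > 0 and -band < (i - j) < band:
                H[i, j] = 0.0
                E[i, j] = _NEG
                F[i, j] = _NEG
                continue
            # E: gap in query (consume subject; move left)
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
            # F: gap in subject (consume query; move up)
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            d = H[i - 1, j - 1] + S[i - 1, j - 1]
            u = F[i, j]
            l = E[i, j]
            h = 0.0
            p = _STOP
            if d >= u and d >= l and d > 0.0:
                h = d
                p = _DIAG
            elif u >= l and u > 0.0:
                h = u
                p = _UP
            elif l > 0.0:
                h = l
                p = _LEFT
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, ptrH, ptrE, ptrF, best, bi, bj


@njit(cache=True)
def _nw_fill(S, gap_open, gap_extend):
    """Needleman-Wunsch affine fill over a dense pair-score matrix."""
    n, m = S.shape
    H = np.full((n + 1, m + 1), _NEG)
    E = np.full((n + 1, m + 1), _NEG)
    F = np.full((n + 1, m + 1), _NEG)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -gap_open - (j - 1) * gap_extend
        H[0, j] = E[0, j]
        ptrH[0, j] = _LEFT
        ptrE[0, j] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        F[i, 0] = -gap_open - (i - 1) * gap_extend
        H[i, 0] = F[i, 0]
        ptrH[i, 0] = _UP
        ptrF[i, 0] = 1 if i > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            d = H[i - 1, j - 1] + S[i - 1, j - 1]
            u = F[i, j]
            l = E[i, j]
            if d >= u and d >= l:
                H[i, j] = d
                ptrH[i, j] = _DIAG
            elif u >= l:
                H[i, j] = u
                ptrH[i, j] = _UP
            else:
                H[i, j] = l
                ptrH[i, j] = _LEFT
    return H, E, F, ptrH, ptrE, ptrF


@njit(cache=True)
def _dotplot_fill(S, window):
    n, m = S.shape
    half = window // 2
    D = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            acc = 0.0
            for k in range(-half, half + 1):
                ii = i + k
                jj = j + k
                if 0 <= ii < n and 0 <= jj < m:
                    acc += S[ii, jj]
            D[i, j] = acc
    return D


# ---------------------------------------------------------------------------
# traceback helpers


def _traceback_local(ptrH, ptrE, ptrF, bi, bj):
    cols: list[tuple[int | None, int | None]] = []
    i, j = bi, bj
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            p = ptrH[i, j]
            if p == _STOP:
                break
            if p == _DIAG:
                cols.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif p == _UP:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            cols.append((i - 1, None))
            ext = ptrF[i, j]
            i -= 1
            state = "F" if ext else "H"
        else:  # E
            cols.append((None, j - 1))
            ext = ptrE[i, j]
            j -= 1
            state = "E" if ext else "H"
    cols.reverse()
    return cols


def _traceback_global(ptrH, ptrE, ptrF, n, m):
    cols: list[tuple[int | None, int | None]] = []
    i, j = n, m
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            p = ptrH[i, j]
            if p == _DIAG:
                cols.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif p == _UP:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            cols.append((i - 1, None))
            ext = ptrF[i, j]
            i -= 1
            state = "F" if ext else "H"
        else:
            cols.append((None, j - 1))
            ext = ptrE[i, j]
            j -= 1
            state = "E" if ext else "H"
    cols.reverse()
    return cols


def _intervals_from_columns(cols):
    qs = [q for q, _ in cols if q is not None]
    ss = [s for _, s in cols if s is not None]
    qi = (min(qs), max(qs) + 1) if qs else (0, 0)
    si = (min(ss), max(ss) + 1) if ss else (0, 0)
    return qi, si


# ---------------------------------------------------------------------------
# public API


def local_align_matrix(S: np.ndarray, gap_open: float, gap_extend: float,
                       band: int = 0) -> LocalAlignmentResult:
    """Optimal affine-gap local alignment over a dense pair-score matrix."""
    S = np.ascontiguousarray(S, dtype=np.float64)
    _, _, _, ptrH, ptrE, ptrF, best, bi, bj = _sw_fill(
        S, float(gap_open), float(gap_extend), int(band)
    )
    if best <= 0.0:
        return LocalAlignmentResult(0.0, (0, 0), (0, 0), [])
    cols = _traceback_local(ptrH, ptrE, ptrF, bi, bj)
    qi, si = _intervals_from_columns(cols)
    return LocalAlignmentResult(float(best), qi, si, cols)


def global_align_matrix(S: np.ndarray, gap_open: float,
                        gap_extend: float) -> GlobalAlignmentResult:
    """Optimal affine-gap global alignment over a dense pair-score matrix."""
    S = np.ascontiguousarray(S, dtype=np.float64)
    n, m = S.shape
    H, _, _, ptrH, ptrE, ptrF = _nw_fill(S, float(gap_open), float(gap_extend))
    cols = _traceback_global(ptrH, ptrE, ptrF, n, m)
    return GlobalAlignmentResult(float(H[n, m]), cols)


def local_align(a, b, scheme: ScoringScheme = DEFAULT_SCHEME) -> LocalAlignmentResult:
    """Smith-Waterman local alignment of two sequences with affine gaps.

    The score is an integer under an integer substitution matrix; intervals
    are empty when no positive-scoring alignment exists.
    """
    ra, rb = _residues(a), _residues(b)
    S = scheme.pair_scores(encode(ra), encode(rb))
    res = local_align_matrix(S, scheme.gap_open, scheme.gap_extend)
    res.score = int(round(res.score))
    return res


def global_align(a, b, scheme: ScoringScheme = DEFAULT_SCHEME) -> GlobalAlignmentResult:
    """Needleman-Wunsch global alignment of two sequences with affine gaps."""
    ra, rb = _residues(a), _residues(b)
    S = scheme.pair_scores(encode(ra), encode(rb))
    res = global_align_matrix(S, scheme.gap_open, scheme.gap_extend)
    res.score = int(round(res.score))
    return res


def dotplot(a, b, window: int = 15,
            scheme: ScoringScheme = DEFAULT_SCHEME) -> DotPlot:
    """Dotlet-style windowed similarity plot of ``a`` against ``b``.

    Entry (i, j) sums substitution scores along the diagonal window centred
    at (i, j); the window is truncated at sequence edges.  Window must be
    odd and no longer than the shorter sequence.
    """
    ra, rb = _residues(a), _residues(b)
    if window % 2 == 0:
        raise ValueError(f"dot-plot window must be odd, got {window}")
    if window > min(len(ra), len(rb)):
        raise ValueError("dot-plot window exceeds the shorter sequence")
    S = scheme.pair_scores(encode(ra), encode(rb)).astype(np.float64)
    return DotPlot(window=window, matrix=_dotplot_fill(S, window))


def self_offdiagonal_align(s, scheme: ScoringScheme = DEFAULT_SCHEME,
                           exclusion_band: int = 20,
                           mask: np.ndarray | None = None) -> LocalAlignmentResult:
    """Best local alignment of a sequence against itself away from the
    main diagonal: cells with |i - j| < exclusion_band are forbidden.

    This is the seed operation for tandem-repeat discovery: a strong
    off-diagonal alignment is an internal duplication.  ``mask`` (boolean,
    True = position unavailable) removes already-claimed positions from
    both axes.
    """
    rs = _residues(s)
    if exclusion_band < 1:
        raise ValueError("exclusion_band must be >= 1")
    if exclusion_band >= len(rs):
        raise ValueError(
            f"exclusion_band {exclusion_band} >= sequence length {len(rs)}"
        )
    idx = encode(rs)
    S = scheme.pair_scores(idx, idx).astype(np.float64)
    if mask is not None:
        S[mask, :] = _NEG / 1e6
        S[:, mask] = _NEG / 1e6
    res = local_align_matrix(S, scheme.gap_open, scheme.gap_extend,
                             band=exclusion_band)
    res.score = float(round(res.score))
    return res


def write_dotplot_tsv(dp: DotPlot, path) -> None:
    np.savetxt(path, dp.matrix, fmt="%.1f", delimiter="\t")
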