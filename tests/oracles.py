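"""Independent oracles for the dynamic-programming engines.

These deliberately avoid the matrix-fill formulation of the package: the
alignment oracles enumerate alignment paths (pure recursion for small
inputs; a memoised suffix recursion for slightly longer ones), and the
HMM oracle enumerates every state path explicitly.  They exist only to
cross-check the fast implementations on tiny inputs.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from flagellarch.hmm import EXIT_PROB, ProfileHMM
from flagellarch.scoring import RESIDUE_INDEX, ScoringScheme

NEG = float("-inf")


# ---------------------------------------------------------------------------
# pairwise alignment oracles


def brute_global_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Pure path enumeration (no memoisation): max global alignment score."""
    sub = scheme.substitution
    go, ge = scheme.gap_open, scheme.gap_extend
    ai = [RESIDUE_INDEX[c] for c in a]
    bi = [RESIDUE_INDEX[c] for c in b]

    def rec(i: int, j: int, prev: str) -> float:
        if i == len(ai) and j == len(bi):
            return 0.0
        best = NEG
        if i < len(ai) and j < len(bi):
            best = max(best, sub[ai[i], bi[j]] + rec(i + 1, j + 1, "M"))
        if i < len(ai):
            cost = ge if prev == "F" else go
            best = max(best, -cost + rec(i + 1, j, "F"))
        if j < len(bi):
            cost = ge if prev == "E" else go
            best = max(best, -cost + rec(i, j + 1, "E"))
        return best

    return rec(0, 0, "M")


def memo_global_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Memoised suffix recursion over (i, j, previous-move)."""
    sub = scheme.substitution
    go, ge = scheme.gap_open, scheme.gap_extend
    ai = tuple(RESIDUE_INDEX[c] for c in a)
    bi = tuple(RESIDUE_INDEX[c] for c in b)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(ai) and j == len(bi):
            return 0.0
        best = NEG
        if i < len(ai) and j < len(bi):
            best = max(best, sub[ai[i], bi[j]] + rec(i + 1, j + 1, "M"))
        if i < len(ai):
            best = max(best, -(ge if prev == "F" else go) + rec(i + 1, j, "F"))
        if j < len(bi):
            best = max(best, -(ge if prev == "E" else go) + rec(i, j + 1, "E"))
        return best

    return rec(0, 0, "M")


def memo_local_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Best local alignment score by memoised extension from every start.

    An optimal local alignment under positive gap penalties starts and
    ends with an aligned pair, so extensions may stop at any point (score
    contribution 0 from stopping).
    """
    sub = scheme.substitution
    go, ge = scheme.gap_open, scheme.gap_extend
    ai = tuple(RESIDUE_INDEX[c] for c in a)
    bi = tuple(RESIDUE_INDEX[c] for c in b)

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, prev: str) -> float:
        best = 0.0  # stop here
        if i < len(ai) and j < len(bi):
            best = max(best, sub[ai[i], bi[j]] + ext(i + 1, j + 1, "M"))
        if i < len(ai):
            best = max(best, -(ge if prev == "F" else go) + ext(i + 1, j, "F"))
        if j < len(bi):
            best = max(best, -(ge if prev == "E" else go) + ext(i, j + 1, "E"))
        return best

    best = 0.0
    for i in range(len(ai)):
        for j in range(len(bi)):
            best = max(best, sub[ai[i], bi[j]] + ext(i + 1, j + 1, "M"))
    return best


def brute_local_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Pure enumeration over all substring pairs and their global paths."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(
                        best,
                        brute_global_score(a[i1:i2], b[j1:j2], scheme),
                    )
    return best


# ---------------------------------------------------------------------------
# profile HMM path enumeration


def _em_odds(hmm: ProfileHMM, k: int, ch: str) -> float:
    idx = RESIDUE_INDEX[ch]
    if idx >= 20:
        return 1.0
    return hmm.match_em[k, idx] / hmm.background[idx]


def _ins_odds(hmm: ProfileHMM, ch: str) -> float:
    idx = RESIDUE_INDEX[ch]
    if idx >= 20:
        return 1.0
    return hmm.insert_em[idx] / hmm.background[idx]


def enumerate_hmm_paths(hmm: ProfileHMM, seq: str):
    """All local state paths with their odds weight.

    Returns (forward_bits, viterbi_bits): log2 of the summed and of the
    maximal path odds, matching the model topology of the implementation
    (uniform entry 1/L into any match state, early exit EXIT_PROB from
    internal match states, mandatory exit from the last).
    """
    L = hmm.length
    n = len(seq)
    tau = EXIT_PROB if L > 1 else 1.0
    cont = 1.0 - tau
    weights: list[float] = []

    def from_match(k: int, pos: int, odds: float) -> None:
        # arrived in M_k having just emitted seq[pos-1] (1-based pos)
        if k == L:
            weights.append(odds)  # mandatory exit
            return
        weights.append(odds * tau)  # early exit
        if pos < n:
            w = odds * cont * hmm.t_mm[k]
            from_match(k + 1, pos + 1, w * _em_odds(hmm, k + 1, seq[pos]))
        if pos < n:
            from_insert(k, pos + 1,
                        odds * cont * hmm.t_mi[k] * _ins_odds(hmm, seq[pos]))
        if k + 1 < L:
            from_delete(k + 1, pos, odds * cont * hmm.t_md[k])

    def from_insert(k: int, pos: int, odds: float) -> None:
        if odds == 0.0:
            return
        if pos < n:
            from_match(k + 1, pos + 1,
                       odds * hmm.t_im[k] * _em_odds(hmm, k + 1, seq[pos]))
            from_insert(k, pos + 1, odds * hmm.t_ii[k] * _ins_odds(hmm, seq[pos]))
        if k + 1 < L:
            from_delete(k + 1, pos, odds * hmm.t_id[k])

    def from_delete(k: int, pos: int, odds: float) -> None:
        if odds == 0.0:
            return
        if pos < n:
            from_match(k + 1, pos + 1,
                       odds * hmm.t_dm[k] * _em_odds(hmm, k + 1, seq[pos]))
            from_insert(k, pos + 1, odds * hmm.t_di[k] * _ins_odds(hmm, seq[pos]))
        if k + 1 < L:
            from_delete(k + 1, pos, odds * hmm.t_dd[k])

    entry = 1.0 / L
    for start in range(n):  # 0-based index of first emitted residue
        for k in range(1, L + 1):
            from_match(k, start + 1,
                       entry * _em_odds(hmm, k, seq[start]))
    if not weights:
        return NEG, NEG
    total = float(np.sum(weights))
    return math.log2(total), math.log2(max(weights))


def core_transition_mass(hmm: ProfileHMM, length: int) -> float:
    """Total probability (transitions x entry/exit only) of core paths that
    emit exactly ``length`` residues; emissions sum out to 1."""
    L = hmm.length
    tau = EXIT_PROB if L > 1 else 1.0
    cont = 1.0 - tau
    total = 0.0

    def from_match(k: int, emitted: int, p: float) -> None:
        nonlocal total
        if emitted > length:
            return
        if k == L:
            if emitted == length:
                total += p
            return
        if emitted == length:
            total += p * tau
        from_match(k + 1, emitted + 1, p * cont * hmm.t_mm[k])
        from_insert(k, emitted + 1, p * cont * hmm.t_mi[k])
        if k + 1 < L:
            from_delete(k + 1, emitted, p * cont * hmm.t_md[k])

    def from_insert(k: int, emitted: int, p: float) -> None:
        if emitted > length or p == 0.0:
            return
        from_match(k + 1, emitted + 1, p * hmm.t_im[k])
        from_insert(k, emitted + 1, p * hmm.t_ii[k])
        if k + 1 < L:
            from_delete(k + 1, emitted, p * hmm.t_id[k])

    def from_delete(k: int, emitted: int, p: float) -> None:
        if p == 0.0:
            return
        from_match(k + 1, emitted + 1, p * hmm.t_dm[k])
        from_insert(k, emitted + 1, p * hmm.t_di[k])
        if k + 1 < L:
            from_delete(k + 1, emitted, p * hmm.t_dd[k])

    for k in range(1, L + 1):
        from_match(k, 1, 1.0 / L)
    return total
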