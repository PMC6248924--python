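"""Substitution scoring for protein alignment.

The default scheme is BLOSUM62 with affine gap penalties 11/1 — the
community-standard choice for protein local alignment.  ``X`` scores 0
against every residue (including itself) so ambiguity never attracts or
repels an alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import ALPHABET

#: Index of each residue in the 21-letter alphabet (20 amino acids + X).
RESIDUE_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
N_RESIDUES = len(ALPHABET)  # 21; index 20 is X


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as int8 alphabet indices."""
    try:
        return np.array([RESIDUE_INDEX[c] for c in residues], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r}") from exc


def _blosum62_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((N_RESIDUES, N_RESIDUES), dtype=np.int32)
    for i, a in enumerate(ALPHABET[:-1]):
        for j, b in enumerate(ALPHABET[:-1]):
            mat[i, j] = int(blosum[a][b])
    # X row/column already zero
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Symmetric substitution matrix plus affine gap penalties.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.
    """

    substitution: np.ndarray = field(default_factory=_blosum62_matrix)
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        sub = np.asarray(self.substitution, dtype=np.int32)
        if sub.shape != (N_RESIDUES, N_RESIDUES):
            raise ValueError(
                f"substitution matrix must be {N_RESIDUES}x{N_RESIDUES}, got {sub.shape}"
            )
        if not np.array_equal(sub, sub.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        object.__setattr__(self, "substitution", sub)

    def score(self, a: str, b: str) -> int:
        """Substitution score of one residue pair."""
        return int(self.substitution[RESIDUE_INDEX[a], RESIDUE_INDEX[b]])

    def pair_scores(self, a_idx: np.ndarray, b_idx: np.ndarray) -> np.ndarray:
        """Dense (len(a), len(b)) matrix of substitution scores."""
        return self.substitution[np.ix_(a_idx.astype(int), b_idx.astype(int))]


DEFAULT_SCHEME = ScoringScheme()


def reduced_alphabet_scheme(match: int = 3, mismatch: int = -2,
                            gap_open: int = 4, gap_extend: int = 1) -> ScoringScheme:
    """A simple match/mismatch scheme, handy for small exhaustive tests."""
    sub = np.full((N_RESIDUES, N_RESIDUES), mismatch, dtype=np.int32)
    np.fill_diagonal(sub, match)
    sub[-1, :] = 0
    sub[:, -1] = 0
    return ScoringScheme(substitution=sub, gap_open=gap_open, gap_extend=gap_extend)
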