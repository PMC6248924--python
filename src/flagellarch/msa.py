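"""Progressive multiple alignment and gap-column trimming.

The aligner merges profiles leaf-to-root along a neighbor-joining guide
tree, scoring profile columns by the mean pairwise substitution score
(gaps score 0 against everything).  Trimming removes columns above a gap
occupancy threshold and returns an index map back to original columns,
giving the trimmed core alignment the phylogeny is built on.

The module is deterministic: no randomness, and input order only matters
through sequence content.
"""

from __future__ import annotations

import numpy as np

from .pairwise import global_align, global_align_matrix
from .phylo import DistanceMatrix, neighbor_joining
from .scoring import DEFAULT_SCHEME, N_RESIDUES, ScoringScheme, encode
from .seqio import GAP, MultipleAlignment, SequenceRecord

Profile = list[tuple[str, str]]  # (id, gapped row)


def _profile_counts(profile: Profile) -> np.ndarray:
    """(columns, 21) residue counts; gaps contribute nothing."""
    length = len(profile[0][1])
    counts = np.zeros((length, N_RESIDUES))
    for _, row in profile:
        for j, ch in enumerate(row):
            if ch != GAP:
                counts[j, encode(ch)[0]] += 1
    return counts


def _merge(pa: Profile, pb: Profile, scheme: ScoringScheme) -> Profile:
    ca = _profile_counts(pa)
    cb = _profile_counts(pb)
    # mean pairwise substitution score between columns; gap pairs score 0
    S = (ca @ scheme.substitution @ cb.T) / (len(pa) * len(pb))
    res = global_align_matrix(S, scheme.gap_open, scheme.gap_extend)
    rows_a = ["" for _ in pa]
    rows_b = ["" for _ in pb]
    for ci, cj in res.aligned_columns:
        for r, (_, row) in enumerate(pa):
            rows_a[r] += row[ci] if ci is not None else GAP
        for r, (_, row) in enumerate(pb):
            rows_b[r] += row[cj] if cj is not None else GAP
    return [(rid, rows_a[r]) for r, (rid, _) in enumerate(pa)] + [
        (rid, rows_b[r]) for r, (rid, _) in enumerate(pb)
    ]


def _guide_order(records: list[SequenceRecord],
                 scheme: ScoringScheme) -> list[tuple[int, int]]:
    """Merge schedule (pairs of profile slots) from an NJ guide tree."""
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(records[i], records[j], scheme)
            ident = sum(
                1
                for ci, cj in res.aligned_columns
                if ci is not None and cj is not None
                and records[i].residues[ci] == records[j].residues[cj]
            )
            d = 1.0 - ident / max(len(res.aligned_columns), 1)
            dist[i, j] = dist[j, i] = d
    if dist.max() == 0.0:
        # indistinguishable sequences: any merge order is equivalent
        return [(0, j) for j in range(1, n)]
    dm = DistanceMatrix([r.id for r in records], dist)
    tree = neighbor_joining(dm)
    tree.reroot_at_midpoint(update_bipartitions=False)
    slot = {r.id: i for i, r in enumerate(records)}
    schedule: list[tuple[int, int]] = []
    rep: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            rep[id(node)] = slot[node.taxon.label]
        else:
            children = [rep[id(c)] for c in node.child_nodes()]
            acc = children[0]
            for other in children[1:]:
                schedule.append((acc, other))
            rep[id(node)] = acc
    return schedule


def progressive_msa(records: list[SequenceRecord],
                    scheme: ScoringScheme = DEFAULT_SCHEME) -> MultipleAlignment:
    """Progressively align sequences along an NJ guide tree.

    Ungapping any output row reproduces the corresponding input exactly.
    """
    if len(records) < 2:
        raise ValueError("progressive MSA needs at least 2 sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in MSA input")
    profiles: dict[int, Profile] = {
        i: [(r.id, r.residues)] for i, r in enumerate(records)
    }
    if len(records) == 2:
        merged = _merge(profiles[0], profiles[1], scheme)
    else:
        for a, b in _guide_order(records, scheme):
            profiles[a] = _merge(profiles[a], profiles[b], scheme)
            del profiles[b]
        (merged,) = profiles.values()
    by_id = dict(merged)
    return MultipleAlignment([(r.id, by_id[r.id]) for r in records])


def trim_gap_columns(msa: MultipleAlignment, max_gap_fraction: float = 0.5
                     ) -> tuple[MultipleAlignment, list[int]]:
    """Drop columns whose gap fraction exceeds the threshold.

    Returns the trimmed alignment plus the list of original column indices
    kept (trimmed column j came from original column index_map[j]).
    """
    if not (0.0 < max_gap_fraction <= 1.0):
        raise ValueError("max_gap_fraction must be in (0, 1]")
    kept = [
        j for j in range(msa.length) if msa.gap_fraction(j) <= max_gap_fraction
    ]
    if not kept:
        raise ValueError("trimming removed every column")
    return msa.slice_columns(kept), kept
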