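"""Core-domain phylogenetics: distances, neighbor joining, and congruence.

The flagellin phylogeny is built from the conserved N-/C-terminal core
(the discontinuous segments folding into the D0/D1 domains) only — the
hypervariable central insert is excluded.  Trees are inferred by neighbor
joining on p- or Poisson-corrected distances; congruence between the repeat
tree and the flagellin tree is measured with the Robinson-Foulds metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .seqio import GAP, MultipleAlignment, write_tsv

#: Poisson-corrected distances are capped here so saturated pairs stay finite.
MAX_POISSON_DISTANCE = 5.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(m)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(m < -1e-12):
            raise ValueError("distances must be non-negative")
        self.matrix = np.clip(m, 0.0, None)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class TreeComparison:
    """Robinson-Foulds comparison of two unrooted leaf-labelled trees."""

    rf_distance: int
    max_rf: int

    @property
    def normalised(self) -> float:
        return self.rf_distance / self.max_rf if self.max_rf > 0 else 0.0


# ---------------------------------------------------------------------------
# distances


def core_distance_matrix(msa: MultipleAlignment,
                         model: str = "poisson_corrected") -> DistanceMatrix:
    """Pairwise distances over shared non-gap columns of a trimmed core MSA.

    ``p_distance`` is the mismatch fraction; ``poisson_corrected`` applies
    -ln(1 - p), capped at :data:`MAX_POISSON_DISTANCE`.  A pair sharing no
    columns is an error naming the pair.
    """
    if model not in ("p_distance", "poisson_corrected"):
        raise ValueError(f"unknown distance model {model!r}")
    if msa.n_rows < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    ids = msa.ids
    rows = [np.frombuffer(row.encode(), dtype="S1") for _, row in msa.rows]
    gap = GAP.encode()
    unknown = b"X"
    n = len(rows)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = (
                (rows[i] != gap) & (rows[j] != gap)
                & (rows[i] != unknown) & (rows[j] != unknown)
            )
            shared = int(usable.sum())
            if shared == 0:
                raise ValueError(
                    f"sequences {ids[i]!r} and {ids[j]!r} share no aligned columns"
                )
            p = float((rows[i][usable] != rows[j][usable]).sum()) / shared
            if model == "p_distance":
                d = p
            else:
                cap_p = 1.0 - math.exp(-MAX_POISSON_DISTANCE)
                d = -math.log(1.0 - min(p, cap_p))
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(list(ids), mat)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographic order of the
    clusters' smallest leaf labels, so the result is independent of input
    row order.  Negative branch lengths are clamped to zero with the
    deficit moved onto the sibling branch.  On additive matrices NJ is
    exact in both topology and branch lengths.
    """
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    ns = dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)
    reps = list(dm.labels)  # representative (min leaf) label per cluster
    D = dm.matrix.copy()
    active = list(range(dm.n))

    def join(i: int, j: int, li: float, lj: float) -> int:
        # clamp negatives, moving the deficit to the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li = max(li, 0.0)
        lj = max(lj, 0.0)
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        return len(nodes) - 1

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(k):
            for aj in range(ai + 1, k):
                q = (k - 2) * sub[ai, aj] - r[ai] - r[aj]
                ia, ja = active[ai], active[aj]
                key_lab = tuple(sorted((reps[ia], reps[ja])))
                cand = (q, key_lab, ai, aj)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, ai, aj = best
        ia, ja = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        new_idx = join(ia, ja, li, lj)
        # distances from the new node to the remaining actives
        newD = np.zeros(len(nodes))
        for am in range(k):
            if am in (ai, aj):
                continue
            im = active[am]
            newD[im] = 0.5 * (D[ia, im] + D[ja, im] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new_idx, : new_idx] = newD[:new_idx]
        D[: new_idx, new_idx] = newD[:new_idx]
        active = [x for x in active if x not in (ia, ja)] + [new_idx]

    # final three-way join
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Robinson-Foulds


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon}


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical frozensets of leaf labels.

    Each internal edge splits the leaves; the side not containing the
    lexicographically smallest label is stored, so the representation is
    rooting-independent.
    """
    all_labels = leaf_labels(tree)
    ref = min(all_labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if len(below) <= 1 or len(below) >= len(all_labels) - 1:
            continue
        side = below if ref not in below else all_labels - below
        if 1 < len(side) < len(all_labels) - 1:
            out.add(frozenset(side))
    return out


def rf_congruence(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> TreeComparison:
    """Robinson-Foulds distance between two trees on the same leaf set.

    max_rf is 2(n - 3), the value attained by two fully resolved trees
    sharing no non-trivial splits.  A label mismatch is an error reporting
    the symmetric difference.
    """
    la, lb = leaf_labels(tree_a), leaf_labels(tree_b)
    if la != lb:
        raise ValueError(
            f"leaf label sets differ; symmetric difference: {sorted(la ^ lb)}"
        )
    ba, bb = bipartitions(tree_a), bipartitions(tree_b)
    rf = len(ba ^ bb)
    max_rf = 2 * max(len(la) - 3, 0)
    return TreeComparison(rf_distance=rf, max_rf=max_rf)


def restrict_tree(tree: dendropy.Tree, labels: set[str]) -> dendropy.Tree:
    """Subtree induced by a subset of leaves (copy; original untouched)."""
    sub = tree.clone(depth=1)
    keep = [t for t in sub.taxon_namespace if t.label in labels]
    sub.retain_taxa(keep)
    return sub


def relabel_leaves(tree: dendropy.Tree, mapping) -> dendropy.Tree:
    """Copy of the tree with leaf labels transformed by ``mapping``."""
    out = tree.clone(depth=1)
    for lf in out.leaf_node_iter():
        if lf.taxon is not None:
            lf.taxon.label = mapping(lf.taxon.label)
    return out


# ---------------------------------------------------------------------------
# annotation


def annotate_inserts(tree: dendropy.Tree, architectures: dict,
                     legend_path=None) -> dendropy.Tree:
    """Attach insert length and DE-copy count to every leaf.

    ``architectures`` maps sequence id to an object exposing
    ``insert_length`` and ``de_copies`` (see the repeat-discovery module).
    Missing leaves are an error listing the ids.  Optionally writes a TSV
    legend with one row per leaf.
    """
    missing = sorted(leaf_labels(tree) - set(architectures))
    if missing:
        raise ValueError(f"no architecture for leaves: {missing}")
    rows = []
    for lf in tree.leaf_node_iter():
        arch = architectures[lf.taxon.label]
        insert_len = arch.insert_length
        n_de = len(arch.de_copies)
        lf.annotations.add_new("insert_len", insert_len)
        lf.annotations.add_new("n_de", n_de)
        rows.append({"id": lf.taxon.label, "insert_len": insert_len,
                     "n_de": n_de})
    if legend_path is not None:
        write_tsv(rows, legend_path, ["id", "insert_len", "n_de"])
    return tree


def annotated_newick(tree: dendropy.Tree) -> str:
    """Newick string with ``[&insert_len=...,n_de=...]`` comment tags."""
    return tree.as_string(
        schema="newick", suppress_rooting=True, suppress_annotations=False
    ).strip()
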