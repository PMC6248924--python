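"""Synthetic flagellin evolution with known ground truth.

The generator emulates the comparative setup the analysis assumes: every
flagellin has conserved N-/C-terminal core segments (the discontinuous
D0/D1 material) around a hypervariable central insert.  Depending on the
clade, the insert is plain sequence, a single DE (Domain-Extension) repeat
unit, two tandem DE copies, or two tandem copies separated by a DX insert
carrying a glycine-rich region.  Ancestral segments are drawn once, then
evolved along a known tree by Poisson substitutions and geometric-length
indels; the DE duplication is planted at the most recent common ancestor
of each tandem clade so the two copies diverge along the species tree
afterwards (vertical transmission).

Indels occur strictly inside segments, so planted boundaries shift but
never vanish: ground-truth intervals always index real residues of the
emitted sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np

from .seqio import AMINO_ACIDS, SequenceRecord

TANDEM_MODELS = {"tandem_DE", "tandem_DE_plus_DX"}
ALL_MODELS = {"none", "single_DE"} | TANDEM_MODELS

#: minimum residues a segment may shrink to under deletion
_MIN_SEGMENT = 5


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    ``divergence`` is the expected number of substitutions per site along
    a root-to-leaf path.  ``leaf_models`` assigns one insert model per
    taxon (in tree leaf order); contiguous tandem blocks share a planted
    duplication at their common ancestor.
    """

    seed: int = 0
    n_taxa: int = 8
    tree_shape: str = "balanced"       # balanced | yule | star
    divergence: float = 0.2
    core_n_length: int = 180
    core_c_length: int = 180
    plain_insert_length: int = 135
    de_length: int = 150
    dx_length: int = 120
    dx_glycine_length: int = 35
    dx_glycine_fraction: float = 0.6
    indel_rate: float = 0.05           # indel events per substitution-unit per site
    indel_extend: float = 0.35         # geometric length parameter
    leaf_models: tuple[str, ...] | None = None
    # decoy (FlgL-like) family: shares the N-terminal helical block with
    # flagellins but has a distinct core elsewhere
    shared_n_block: int = 60
    decoy_core_length: int = 250
    decoy_divergence: float = 0.3

    def resolved_leaf_models(self) -> tuple[str, ...]:
        if self.leaf_models is None:
            return tuple(["tandem_DE_plus_DX"] * self.n_taxa)
        if len(self.leaf_models) != self.n_taxa:
            raise ValueError(
                f"leaf_models has {len(self.leaf_models)} entries for "
                f"{self.n_taxa} taxa"
            )
        bad = set(self.leaf_models) - ALL_MODELS
        if bad:
            raise ValueError(f"unknown insert model(s): {sorted(bad)}")
        return tuple(self.leaf_models)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if "leaf_models" in data and data["leaf_models"] is not None:
            data["leaf_models"] = tuple(data["leaf_models"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml
        from dataclasses import asdict

        data = asdict(self)
        if data["leaf_models"] is not None:
            data["leaf_models"] = list(data["leaf_models"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def validate(self) -> None:
        for name in ("core_n_length", "core_c_length", "plain_insert_length",
                     "de_length", "dx_length", "dx_glycine_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.divergence < 0:
            raise ValueError("divergence must be non-negative")
        if self.dx_glycine_length >= self.dx_length:
            raise ValueError("glycine region must fit inside the DX insert")
        if self.tree_shape not in ("balanced", "yule", "star"):
            raise ValueError(f"unknown tree_shape {self.tree_shape!r}")
        self.resolved_leaf_models()


def oceanospirillales_preset(seed: int = 0, n_taxa: int = 8) -> SyntheticConfig:
    """Giant-flagellin geometry: 180 + 260 + 140 + 260 + 180 = 1,020 aa for
    the tandem-plus-DX leaves, mirroring the scale of the largest
    Oceanospirillales flagellins.  Half the taxa are giant, a quarter carry
    a single DE copy, a quarter are canonical."""
    n_giant = n_taxa // 2
    n_single = max((n_taxa - n_giant) // 2, 1)
    n_plain = n_taxa - n_giant - n_single
    models = ("tandem_DE_plus_DX",) * n_giant + ("single_DE",) * n_single \
        + ("none",) * n_plain
    return SyntheticConfig(
        seed=seed, n_taxa=n_taxa, de_length=260, dx_length=140,
        leaf_models=models,
    )


def canonical_preset(seed: int = 0, n_taxa: int = 8) -> SyntheticConfig:
    """Canonical flagellin geometry: 180 + 135 + 180 = 495 aa, no repeats."""
    return SyntheticConfig(
        seed=seed, n_taxa=n_taxa, leaf_models=("none",) * n_taxa,
    )


@dataclass
class LeafTruth:
    """Planted intervals (0-based half-open) for one emitted sequence."""

    seq_id: str
    model: str
    n_core: tuple[int, int]
    de_copies: list[tuple[int, int]]
    dx: tuple[int, int] | None
    glycine: tuple[int, int] | None
    c_core: tuple[int, int]

    @property
    def insert(self) -> tuple[int, int]:
        return (self.n_core[1], self.c_core[0])


@dataclass
class GroundTruth:
    tree_newick: str
    leaves: dict[str, LeafTruth]
    config: SyntheticConfig

    def tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.tree_newick, schema="newick")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tree_newick": self.tree_newick,
            "leaves": {
                sid: {
                    "model": t.model,
                    "n_core": list(t.n_core),
                    "de_copies": [list(c) for c in t.de_copies],
                    "dx": list(t.dx) if t.dx else None,
                    "glycine": list(t.glycine) if t.glycine else None,
                    "c_core": list(t.c_core),
                }
                for sid, t in self.leaves.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# tree construction


@dataclass
class _Node:
    edge: float
    children: list["_Node"] = field(default_factory=list)
    leaf: int | None = None


def _balanced(indices: list[int], edge: float, depth_left: int) -> _Node:
    if len(indices) == 1:
        return _Node(edge=edge, leaf=indices[0])
    mid = (len(indices) + 1) // 2
    node = _Node(edge=edge)
    node.children = [
        _balanced(indices[:mid], edge, depth_left - 1),
        _balanced(indices[mid:], edge, depth_left - 1),
    ]
    return node


def _build_tree(cfg: SyntheticConfig, rng: np.random.Generator) -> _Node:
    n = cfg.n_taxa
    if cfg.tree_shape == "star":
        root = _Node(edge=0.0)
        root.children = [_Node(edge=cfg.divergence, leaf=i) for i in range(n)]
        return root
    if cfg.tree_shape == "balanced":
        depth = max(int(np.ceil(np.log2(max(n, 2)))), 1)
        root = _balanced(list(range(n)), cfg.divergence / depth, depth)
        root.edge = 0.0
        return root
    # yule: grow by splitting a uniformly chosen leaf, unit edges, then
    # rescale so the deepest leaf path equals the target divergence
    root = _Node(edge=0.0)
    root.children = [_Node(edge=1.0, leaf=0), _Node(edge=1.0, leaf=1)]
    leaves = list(root.children)
    for nxt in range(2, n):
        pick = leaves.pop(int(rng.integers(len(leaves))))
        old_leaf = pick.leaf
        pick.leaf = None
        pick.children = [_Node(edge=1.0, leaf=old_leaf), _Node(edge=1.0, leaf=nxt)]
        leaves.extend(pick.children)

    def max_depth(node: _Node) -> float:
        if not node.children:
            return node.edge
        return node.edge + max(max_depth(c) for c in node.children)

    scale = cfg.divergence / max_depth(root) if cfg.divergence > 0 else 0.0

    def rescale(node: _Node) -> None:
        node.edge *= scale
        for c in node.children:
            rescale(c)

    rescale(root)
    return root


def _leaf_ids(node: _Node) -> list[int]:
    if node.leaf is not None:
        return [node.leaf]
    out: list[int] = []
    for c in node.children:
        out.extend(_leaf_ids(c))
    return out


def _to_newick(node: _Node, names: list[str]) -> str:
    if node.leaf is not None:
        return f"{names[node.leaf]}:{node.edge:.6f}"
    inner = ",".join(_to_newick(c, names) for c in node.children)
    return f"({inner}):{node.edge:.6f}"


# ---------------------------------------------------------------------------
# sequence evolution


def _draw(rng: np.random.Generator, length: int,
          freqs: np.ndarray | None = None) -> str:
    if freqs is None:
        freqs = np.full(20, 0.05)
    idx = rng.choice(20, size=length, p=freqs)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _glycine_freqs(fraction: float) -> np.ndarray:
    freqs = np.full(20, (1.0 - fraction) / 19.0)
    freqs[AMINO_ACIDS.index("G")] = fraction
    return freqs


def _evolve_segment(seq: str, branch: float, cfg: SyntheticConfig,
                    rng: np.random.Generator) -> str:
    """Poisson substitutions plus geometric indels, confined to the segment."""
    if branch <= 0 or not seq:
        return seq
    chars = list(seq)
    # substitutions: each site hit with P = 1 - exp(-branch)
    p_hit = 1.0 - np.exp(-branch)
    hits = np.nonzero(rng.random(len(chars)) < p_hit)[0]
    for i in hits:
        choices = AMINO_ACIDS.replace(chars[i], "")
        chars[i] = choices[int(rng.integers(len(choices)))]
    # indels
    n_indels = rng.poisson(cfg.indel_rate * branch * len(chars))
    for _ in range(n_indels):
        length = int(rng.geometric(cfg.indel_extend))
        if rng.random() < 0.5 and len(chars) - length >= _MIN_SEGMENT:
            pos = int(rng.integers(max(len(chars) - length + 1, 1)))
            del chars[pos : pos + length]
        else:
            pos = int(rng.integers(len(chars) + 1))
            chars[pos:pos] = list(_draw(rng, length))
    return "".join(chars)


def _ancestral_segments(cfg: SyntheticConfig) -> dict[str, str]:
    # one sub-seeded stream per segment, so configs sharing a seed share
    # the ancestors of every segment whose length they agree on
    def rng_for(i: int) -> np.random.Generator:
        return np.random.default_rng([cfg.seed, 101, i])

    pre = (cfg.dx_length - cfg.dx_glycine_length) // 2
    post = cfg.dx_length - cfg.dx_glycine_length - pre
    return {
        "ncore": _draw(rng_for(0), cfg.core_n_length),
        "plain": _draw(rng_for(1), cfg.plain_insert_length),
        "de": _draw(rng_for(2), cfg.de_length),
        "dx_pre": _draw(rng_for(3), pre),
        "glyc": _draw(rng_for(4), cfg.dx_glycine_length,
                      _glycine_freqs(cfg.dx_glycine_fraction)),
        "dx_post": _draw(rng_for(5), post),
        "ccore": _draw(rng_for(6), cfg.core_c_length),
        "decoy_core": _draw(rng_for(7), cfg.decoy_core_length),
    }


_SEGMENT_ORDER = ["ncore", "plain", "de", "de1", "de2", "dx_pre", "glyc",
                  "dx_post", "ccore", "decoy_core"]


def _assemble(sid: str, model: str, seg: dict[str, str]) -> tuple[SequenceRecord, LeafTruth]:
    parts: list[tuple[str, str]] = [("n_core", seg["ncore"])]
    if model == "none":
        parts.append(("plain", seg["plain"]))
    elif model == "single_DE":
        parts.append(("de1", seg.get("de1", seg["de"])))
    elif model == "tandem_DE":
        parts.append(("de1", seg.get("de1", seg["de"])))
        parts.append(("de2", seg.get("de2", seg["de"])))
    elif model == "tandem_DE_plus_DX":
        parts.append(("de1", seg.get("de1", seg["de"])))
        parts.append(("dx_pre", seg["dx_pre"]))
        parts.append(("glyc", seg["glyc"]))
        parts.append(("dx_post", seg["dx_post"]))
        parts.append(("de2", seg.get("de2", seg["de"])))
    else:  # pragma: no cover - validated upstream
        raise ValueError(f"unknown model {model!r}")
    parts.append(("c_core", seg["ccore"]))

    bounds: dict[str, tuple[int, int]] = {}
    pos = 0
    residues = []
    for name, s in parts:
        bounds[name] = (pos, pos + len(s))
        residues.append(s)
        pos += len(s)
    de_copies = [bounds[k] for k in ("de1", "de2") if k in bounds]
    dx = None
    glyc = None
    if "dx_pre" in bounds:
        dx = (bounds["dx_pre"][0], bounds["dx_post"][1])
        glyc = bounds["glyc"]
    truth = LeafTruth(
        seq_id=sid, model=model, n_core=bounds["n_core"],
        de_copies=de_copies, dx=dx, glycine=glyc, c_core=bounds["c_core"],
    )
    return SequenceRecord(sid, "".join(residues)), truth


def generate(config: SyntheticConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """Emit one synthetic dataset plus its ground truth.

    Identical configs produce byte-identical output.  The DE duplication is
    planted at the root of every maximal clade whose leaves all carry a
    tandem model; below that node the two copies evolve independently.
    """
    config.validate()
    models = config.resolved_leaf_models()
    rng_tree = np.random.default_rng([config.seed, 7])
    rng_evo = np.random.default_rng([config.seed, 11])
    root = _build_tree(config, rng_tree)
    names = [f"t{i + 1:02d}" for i in range(config.n_taxa)]
    ancestral = _ancestral_segments(config)

    records: list[SequenceRecord] = []
    truths: dict[str, LeafTruth] = {}

    def walk(node: _Node, segments: dict[str, str]) -> None:
        segments = {
            k: _evolve_segment(v, node.edge, config, rng_evo)
            for k, v in segments.items()
        }
        under = _leaf_ids(node)
        if ("de1" not in segments
                and all(models[i] in TANDEM_MODELS for i in under)):
            segments["de1"] = segments["de"]
            segments["de2"] = segments["de"]
        if node.leaf is not None:
            rec, truth = _assemble(names[node.leaf], models[node.leaf], segments)
            records.append(rec)
            truths[rec.id] = truth
            return
        for child in node.children:
            walk(child, dict(segments))

    walk(root, ancestral)
    records.sort(key=lambda r: r.id)
    newick = "(" + ",".join(_to_newick(c, names) for c in root.children) + ");"
    truth = GroundTruth(tree_newick=newick, leaves=truths, config=config)
    return records, truth


# ---------------------------------------------------------------------------
# reference sets and decoys (classifier training / evaluation material)


def generate_flagellin_set(config: SyntheticConfig, n: int,
                           divergence: float | None = None,
                           model: str = "none", tag: str = "fla",
                           stream: int = 23) -> tuple[list[SequenceRecord], GroundTruth]:
    """A star-tree family of flagellins with the given insert model —
    training or evaluation material drawn from the same ancestors as
    :func:`generate` for the same seed."""
    cfg = replace(
        config, n_taxa=n, tree_shape="star",
        divergence=config.divergence if divergence is None else divergence,
        leaf_models=(model,) * n,
    )
    rng_evo = np.random.default_rng([config.seed, stream])
    root = _build_tree(cfg, rng_evo)
    names = [f"{tag}{i + 1:03d}" for i in range(n)]
    ancestral = _ancestral_segments(config)
    records: list[SequenceRecord] = []
    truths: dict[str, LeafTruth] = {}
    for child in root.children:
        segments = {
            k: _evolve_segment(v, child.edge, cfg, rng_evo)
            for k, v in ancestral.items()
        }
        rec, truth = _assemble(names[child.leaf], model, segments)
        records.append(rec)
        truths[rec.id] = truth
    newick = "(" + ",".join(_to_newick(c, names) for c in root.children) + ");"
    return records, GroundTruth(tree_newick=newick, leaves=truths, config=cfg)


def generate_decoys(config: SyntheticConfig, n: int,
                    tag: str = "flgl", stream: int = 29) -> list[SequenceRecord]:
    """FlgL-like decoys: the first ``shared_n_block`` residues descend from
    the flagellin N-core ancestor (the shared helical block), the rest from
    a distinct decoy core.  Labelled by the ``flgl`` id prefix."""
    ancestral = _ancestral_segments(config)
    shared = ancestral["ncore"][: config.shared_n_block]
    rng = np.random.default_rng([config.seed, stream])
    out = []
    for i in range(n):
        block = _evolve_segment(shared, config.decoy_divergence, config, rng)
        core = _evolve_segment(ancestral["decoy_core"], config.decoy_divergence,
                               config, rng)
        out.append(SequenceRecord(f"{tag}{i + 1:03d}", block + core))
    return out
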