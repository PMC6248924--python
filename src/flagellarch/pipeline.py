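"""End-to-end orchestration of the giant-flagellin analysis.

The full analysis runs in stages: family classification (flagellin vs
FlgL-like) -> size classes and central-insert measurement -> tandem repeat
seeding -> iterative DE discovery -> DX and glycine-rich detection ->
architecture assembly -> core (D0/D1) phylogeny with insert annotation ->
DE-vs-flagellin congruence.  :func:`analyse` drives the stages over
prepared models; :func:`run_synthetic_study` wraps it for generated data
with ground truth (the testing configuration); :func:`run_all` wraps it
for file inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import classify as fc
from . import phylo, repeats
from .hmm import ProfileHMM, build_hmm
from .msa import progressive_msa, trim_gap_columns
from .scoring import DEFAULT_SCHEME, ScoringScheme
from .seqio import (MultipleAlignment, SequenceRecord, read_alignment,
                    read_fasta, write_tsv)
from .simulate import (GroundTruth, SyntheticConfig, generate, generate_decoys,
                       generate_flagellin_set)


@dataclass
class Thresholds:
    """All stage thresholds in one serialisable bundle."""

    evalue: float = 0.1
    ambiguity_band: float = fc.DEFAULT_BAND
    trim_gap_fraction: float = 0.5
    exclusion_band: int = repeats.MIN_REPEAT_LENGTH
    min_dx_length: int = repeats.MIN_DX_LENGTH
    glycine_window: int = 11
    glycine_min_fraction: float = 0.4
    glycine_min_length: int = 20
    max_de_iterations: int = 5


@dataclass
class Models:
    flagellin: ProfileHMM
    flgl: ProfileHMM
    ncore: ProfileHMM
    ccore: ProfileHMM


@dataclass
class AnalysisResult:
    calls: list[fc.FamilyCall]
    sizes: dict[str, fc.SizeClass]
    inserts: dict[str, fc.InsertMeasurement]
    tandem_pairs: list[repeats.RepeatPair]
    discovery: repeats.DiscoveryResult | None
    de_copies: dict[str, list[tuple[int, int]]]
    dx: dict[str, tuple[int, int] | None]
    glycine: dict[str, list[repeats.GlycineRichHit]]
    architectures: dict[str, object]   # FlagellinArchitecture | ArchitectureRejection
    core_tree: object | None           # dendropy.Tree
    de_comparisons: list[phylo.TreeComparison]
    summary: dict = field(default_factory=dict)


def build_models(flagellin_msa: MultipleAlignment, flgl_msa: MultipleAlignment,
                 ncore_msa: MultipleAlignment, ccore_msa: MultipleAlignment
                 ) -> Models:
    return Models(
        flagellin=build_hmm(flagellin_msa, name="flagellin"),
        flgl=build_hmm(flgl_msa, name="flgl"),
        ncore=build_hmm(ncore_msa, name="ncore"),
        ccore=build_hmm(ccore_msa, name="ccore"),
    )


def analyse(records: list[SequenceRecord], models: Models,
            thresholds: Thresholds = Thresholds(), seed: int = 0,
            scheme: ScoringScheme = DEFAULT_SCHEME) -> AnalysisResult:
    """Run every stage over the records; deterministic given the seed."""
    if not records:
        raise ValueError("no input sequences")

    calls = fc.classify(records, models.flagellin, models.flgl,
                        thresholds.ambiguity_band)
    flagellins = [
        r for r, c in zip(records, calls) if c.label == "flagellin"
    ]
    sizes = {r.id: fc.size_class(r) for r in records}
    inserts: dict[str, fc.InsertMeasurement] = {}
    for rec in flagellins:
        inserts[rec.id] = fc.measure_insert(rec, models.ncore, models.ccore)

    # tandem repeat seeding; the repeat-calling threshold is computed once
    # per run from the longest measured insert's shuffled null
    measurable = [
        (rec, inserts[rec.id].interval)
        for rec in flagellins
        if inserts[rec.id].status == "ok"
    ]
    min_score = None
    if measurable:
        longest = max(measurable, key=lambda t: t[1][1] - t[1][0])
        sub = longest[0].residues[longest[1][0]:longest[1][1]]
        if len(sub) >= 2 * thresholds.exclusion_band:
            min_score = repeats.repeat_score_threshold(
                sub, scheme, thresholds.exclusion_band, seed=seed,
            )
    tandem_pairs: list[repeats.RepeatPair] = []
    if min_score is not None:
        for rec, iv in measurable:
            tandem_pairs.extend(repeats.find_tandem_repeats(
                rec, iv, scheme, min_score=min_score,
                exclusion_band=thresholds.exclusion_band, seed=seed,
            ))

    discovery = None
    de_copies: dict[str, list[tuple[int, int]]] = {r.id: [] for r in records}
    if tandem_pairs:
        discovery = repeats.iterative_de_discovery(
            flagellins, tandem_pairs, evalue_threshold=thresholds.evalue,
            max_iter=thresholds.max_de_iterations, seed=seed,
        )
        for h in discovery.hits:
            de_copies[h.seq_id].append(h.interval)
        for sid in de_copies:
            de_copies[sid].sort()

    dx: dict[str, tuple[int, int] | None] = {}
    glyc: dict[str, list[repeats.GlycineRichHit]] = {}
    archs: dict[str, object] = {}
    by_id = {r.id: r for r in records}
    for rec in flagellins:
        meas = inserts[rec.id]
        copies = de_copies.get(rec.id, [])
        dx[rec.id] = repeats.detect_dx(rec, copies, thresholds.min_dx_length)
        glyc[rec.id] = (
            repeats.glycine_rich_scan(
                rec, dx[rec.id], thresholds.glycine_window,
                thresholds.glycine_min_fraction, thresholds.glycine_min_length)
            if dx[rec.id] else []
        )
        if meas.status == "ok":
            n_core = (0, meas.interval[0])
            c_core = (meas.interval[1], len(rec))
            archs[rec.id] = repeats.assemble_architecture(
                rec, n_core, c_core, copies, dx[rec.id], sizes[rec.id]
            )

    # D0/D1 core phylogeny over the measured cores
    core_tree = None
    core_records = []
    for rec, iv in measurable:
        core_seq = rec.residues[: iv[0]] + rec.residues[iv[1]:]
        core_records.append(SequenceRecord(rec.id, core_seq))
    if len(core_records) >= 3:
        core_msa = progressive_msa(core_records, scheme)
        trimmed, _ = trim_gap_columns(core_msa, thresholds.trim_gap_fraction)
        dm = phylo.core_distance_matrix(trimmed)
        core_tree = phylo.neighbor_joining(dm)
        good_archs = {
            sid: a for sid, a in archs.items()
            if isinstance(a, repeats.FlagellinArchitecture)
        }
        if set(ph.taxon.label for ph in core_tree.leaf_node_iter()) <= set(good_archs):
            phylo.annotate_inserts(core_tree, good_archs)

    # DE-vs-flagellin congruence: compare each post-duplication copy tree
    # with the flagellin core tree restricted to the tandem taxa
    de_comparisons: list[phylo.TreeComparison] = []
    if core_tree is not None:
        tandem_ids = sorted(
            sid for sid, copies in de_copies.items() if len(copies) >= 2
        )
        if len(tandem_ids) >= 4:
            species_sub = phylo.restrict_tree(core_tree, set(tandem_ids))
            for c in (0, 1):
                copy_records = [
                    SequenceRecord(sid, by_id[sid].residues[slice(*de_copies[sid][c])])
                    for sid in tandem_ids
                ]
                copy_msa = progressive_msa(copy_records, scheme)
                dm = phylo.core_distance_matrix(copy_msa)
                copy_tree = phylo.neighbor_joining(dm)
                de_comparisons.append(phylo.rf_congruence(copy_tree, species_sub))

    n_by_label = {lab: sum(1 for c in calls if c.label == lab)
                  for lab in ("flagellin", "flgL_like", "ambiguous")}
    summary = {
        "n_records": len(records),
        "n_flagellin": n_by_label["flagellin"],
        "n_flgl_like": n_by_label["flgL_like"],
        "n_ambiguous": n_by_label["ambiguous"],
        "n_giant": sum(1 for s in sizes.values() if s.label == "giant"),
        "n_large": sum(1 for s in sizes.values() if s.label == "large"),
        "n_tandem_pairs": len(tandem_pairs),
        "n_de_instances": 0 if discovery is None else len(discovery.instances),
        "de_iterations": 0 if discovery is None else discovery.n_iterations,
        "de_converged": False if discovery is None else discovery.converged,
        "n_with_dx": sum(1 for v in dx.values() if v is not None),
        "n_glycine_hits": sum(len(v) for v in glyc.values()),
        "de_rf_normalised": [c.normalised for c in de_comparisons],
        "seed": seed,
    }
    return AnalysisResult(
        calls=calls, sizes=sizes, inserts=inserts, tandem_pairs=tandem_pairs,
        discovery=discovery, de_copies=de_copies, dx=dx, glycine=glyc,
        architectures=archs, core_tree=core_tree,
        de_comparisons=de_comparisons, summary=summary,
    )


# ---------------------------------------------------------------------------
# synthetic study (generated data + generated training material)


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    records: list[SequenceRecord]
    truth: GroundTruth
    models: Models
    result: AnalysisResult


def synthetic_models(config: SyntheticConfig, n_train: int = 12) -> Models:
    """Family and core models trained on generator-drawn reference sets."""
    train, train_truth = generate_flagellin_set(
        config, n_train, model="none", tag="trainfla", stream=31
    )
    decoys = generate_decoys(config, n_train, tag="trainflgl", stream=37)
    ncore_recs = []
    ccore_recs = []
    for rec in train:
        t = train_truth.leaves[rec.id]
        ncore_recs.append(rec.slice(*t.n_core))
        ccore_recs.append(rec.slice(*t.c_core))
    return build_models(
        flagellin_msa=progressive_msa(train),
        flgl_msa=progressive_msa(decoys),
        ncore_msa=progressive_msa(ncore_recs),
        ccore_msa=progressive_msa(ccore_recs),
    )


def run_synthetic_study(config: SyntheticConfig,
                        thresholds: Thresholds = Thresholds(),
                        n_train: int = 12) -> SyntheticStudy:
    """Generate a dataset under the config and run the full analysis on it."""
    records, truth = generate(config)
    models = synthetic_models(config, n_train=n_train)
    result = analyse(records, models, thresholds, seed=config.seed)
    result.summary["truth_n_giant"] = sum(
        1 for t in truth.leaves.values() if t.model == "tandem_DE_plus_DX"
    )
    return SyntheticStudy(config=config, records=records, truth=truth,
                          models=models, result=result)


# ---------------------------------------------------------------------------
# file-based run


@dataclass
class RunConfig:
    input_fasta: str
    flagellin_seed: str
    flgl_seed: str
    out_dir: str
    ncore_seed: str | None = None
    ccore_seed: str | None = None
    core_columns: int = 180
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        thr = data.pop("thresholds", None)
        for key in ("input_fasta", "flagellin_seed", "flgl_seed", "out_dir"):
            data.setdefault(key, "")
        cfg = cls(**data)
        if thr:
            cfg.thresholds = Thresholds(**thr)
        return cfg


def _core_slices(msa: MultipleAlignment, n_cols: int
                 ) -> tuple[MultipleAlignment, MultipleAlignment]:
    n = min(n_cols, msa.length // 2)
    return (msa.slice_columns(range(n)),
            msa.slice_columns(range(msa.length - n, msa.length)))


def run_all(config: RunConfig) -> AnalysisResult:
    """File-based end-to-end run: reads inputs, writes per-stage TSVs and a
    provenance-carrying summary JSON into the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_fasta(config.input_fasta)
    fla_msa = read_alignment(config.flagellin_seed, _dialect(config.flagellin_seed))
    flgl_msa = read_alignment(config.flgl_seed, _dialect(config.flgl_seed))
    if config.ncore_seed and config.ccore_seed:
        ncore_msa = read_alignment(config.ncore_seed, _dialect(config.ncore_seed))
        ccore_msa = read_alignment(config.ccore_seed, _dialect(config.ccore_seed))
    else:
        ncore_msa, ccore_msa = _core_slices(fla_msa, config.core_columns)
    models = build_models(fla_msa, flgl_msa, ncore_msa, ccore_msa)
    result = analyse(records, models, config.thresholds, seed=config.seed)
    write_reports(result, out)
    cfg_text = json.dumps(asdict(config), sort_keys=True, default=str)
    result.summary["config_hash"] = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    (out / "summary.json").write_text(json.dumps(result.summary, indent=1))
    return result


def _dialect(path: str) -> str:
    return "clustal" if str(path).endswith((".aln", ".clustal")) else "aligned-fasta"


def write_reports(result: AnalysisResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(
        [
            {"id": c.seq_id, "label": c.label,
             "bits_flagellin": f"{c.score_flagellin:.2f}",
             "bits_flgl": f"{c.score_flgl:.2f}", "margin": f"{c.margin:.2f}"}
            for c in result.calls
        ],
        out / "family_calls.tsv",
        ["id", "label", "bits_flagellin", "bits_flgl", "margin"],
    )
    arch_rows = []
    for sid, arch in sorted(result.architectures.items()):
        if isinstance(arch, repeats.FlagellinArchitecture):
            arch_rows.append({
                "id": sid, "size_class": arch.size.label,
                "length": arch.size.length,
                "insert_len": arch.insert_length,
                "n_de": len(arch.de_copies),
                "dx": "-" if arch.dx is None else f"{arch.dx[0]}..{arch.dx[1]}",
                "architecture": arch.architecture_string,
            })
        else:
            arch_rows.append({"id": sid, "size_class": "REJECTED",
                              "architecture": arch.constraint})
    write_tsv(arch_rows, out / "architectures.tsv",
              ["id", "size_class", "length", "insert_len", "n_de", "dx",
               "architecture"])
    if result.core_tree is not None:
        (out / "core_tree.nwk").write_text(
            result.core_tree.as_string(schema="newick"))
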