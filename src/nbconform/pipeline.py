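"""End-to-end synthetic run: configuration, stage wiring, artifacts.

``run_pipeline`` executes the full chain on generated data — 4C reads to
contact regions, contact regions to gene sets and enrichment, spot tables
to interaction frequencies, expression tables to concordant calls,
junction tables to noise metrics, plus the geometric null — writing plain-
text artifacts into an output directory. Stages read their inputs from the
artifact directory, so a deleted intermediate surfaces as an explicit
missing-input error. Every run records the configuration hash in its
manifest and JSON reports.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contact_genes, expression, fourc, geometry, imaging, io, splicing, synthetic
from .genome import GeneRecord, GenomicInterval, ToyGenome

STAGES = ("simulate", "fourc", "genes", "fish", "expr", "splice", "geometry")


class MissingInputError(FileNotFoundError):
    pass


@dataclass
class RunConfig:
    """All stage parameters and seeds for a reproducible synthetic run."""

    seed: int = 0
    n_reads: int = 100_000
    bin_size: int = 10_000
    window: int = 100_000
    pseudocount: float = 0.1
    threshold: float = 7.0
    extension_window: int = 10_000
    n_permutation_samples: int = 100
    n_genes: int = 200
    class_mix: dict = field(
        default_factory=lambda: {
            "snRNA": 0.05,
            "snoRNA": 0.10,
            "scaRNA": 0.05,
            "histone": 0.05,
            "coding": 0.75,
        }
    )
    n_planted_target_genes: int = 12
    n_cells: int = 500
    p_dep: float = 0.3
    p_indep: float = 0.1
    pixel_size_nm: float = 320.0
    gene_thresh_px: float = 3.0
    cb_thresh_px: float = 5.0
    kd_effect: float = -2.0
    lfc_threshold: float = 1.0
    log2_pseudocount: float = 0.01
    unannot_rate_control: float = 0.1
    unannot_rate_kd: float = 0.2
    nuc_rad: float = 7.7
    ct_rad: float = 3.2
    delta: float = 0.5
    mc_draws: int = 100_000

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingInputError(
            f"stage {stage!r} requires missing input {path}; "
            "run the producing stage first"
        )
    return path


def _write_json(obj: dict, path: Path, cfg: RunConfig) -> None:
    obj = {"config_hash": cfg.config_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def plant_target_genes(
    genes: list[GeneRecord],
    peaks: list[GenomicInterval],
    n: int,
    classes=("snRNA", "snoRNA", "scaRNA", "histone"),
) -> list[GeneRecord]:
    """Relocate up to ``n`` target-class genes to lie inside the planted
    contact peaks (deterministic layout), so class enrichment near contacts
    is recoverable downstream."""
    out = list(genes)
    targets = [i for i, g in enumerate(out) if g.gene_class in classes][:n]
    spacing = 3_000
    slot = 0
    for i in targets:
        peak = peaks[slot % len(peaks)]
        offset = (slot // len(peaks)) * spacing
        start = peak.start + offset
        end = min(start + 1_500, peak.end)
        if end <= start:
            break
        out[i] = GeneRecord(
            out[i].gene_id,
            GenomicInterval(peak.chrom, start, end),
            out[i].gene_class,
            out[i].expression,
        )
        slot += 1
    return out


def run_pipeline(
    config: RunConfig, out_dir: str | Path, stages: list[str] | None = None
) -> dict:
    """Run the requested stages (default: all, in order) into ``out_dir``.

    Returns a summary dict; raises ``MissingInputError`` when a later stage
    is run without its inputs on disk.
    """
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    summary: dict = {"config_hash": cfg.config_hash}
    manifest: dict = {}
    genome = synthetic.default_genome()
    arch = synthetic.default_architecture(genome)

    if "simulate" in stages:
        _stage_simulate(cfg, out, genome, arch, manifest)
    if "fourc" in stages:
        summary["fourc"] = _stage_fourc(cfg, out, genome, manifest)
    if "genes" in stages:
        summary["genes"] = _stage_genes(cfg, out, genome, arch, manifest)
    if "fish" in stages:
        summary["fish"] = _stage_fish(cfg, out, manifest)
    if "expr" in stages:
        summary["expr"] = _stage_expr(cfg, out, manifest)
    if "splice" in stages:
        summary["splice"] = _stage_splice(cfg, out, manifest)
    if "geometry" in stages:
        summary["geometry"] = _stage_geometry(cfg, out, manifest)

    manifest_path = out / "manifest.json"
    existing = {}
    if manifest_path.exists():
        existing = json.loads(manifest_path.read_text()).get("files", {})
    existing.update(manifest)
    manifest_path.write_text(
        json.dumps(
            {"config_hash": cfg.config_hash, "files": existing},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    _write_json({"summary": _jsonable(summary)}, out / "run_summary.json", cfg)
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _stage_simulate(cfg, out, genome, arch, manifest):
    genes = synthetic.generate_genome_annotation(
        genome, cfg.class_mix, n_genes=cfg.n_genes, seed=cfg.seed
    )
    peak_ivs = [iv for iv, _ in arch.cis_peaks + arch.trans_peaks]
    genes = plant_target_genes(genes, peak_ivs, cfg.n_planted_target_genes)

    expr_model = synthetic.ExpressionModel(kd_effect=cfg.kd_effect)
    tables = synthetic.simulate_expression_table(
        expr_model, ["control_1", "control_2", "kd"], seed=cfg.seed, genes=genes
    )
    ctrl_fpkm = tables["fpkm"][tables["condition_map"]["control_1"]].mean(axis=1)
    genes = [
        GeneRecord(g.gene_id, g.interval, g.gene_class, float(ctrl_fpkm[g.gene_id]))
        for g in genes
    ]

    for rep in (1, 2):
        reads = synthetic.simulate_4c_reads(
            arch, genome, cfg.n_reads, seed=cfg.seed + rep
        )
        io.write_bed_reads(reads, out / f"reads_rep{rep}.bed")
        manifest[f"reads_rep{rep}.bed"] = cfg.config_hash
    io.write_bed_genes(genes, out / "genes.bed")
    io.write_gtf_lite(genes, out / "genes.gtf")

    cells = synthetic.simulate_cell_spots(
        synthetic.CellPopulationModel(
            n_cells=cfg.n_cells,
            p_dep=cfg.p_dep,
            p_indep=cfg.p_indep,
            pixel_size=cfg.pixel_size_nm,
            gene_thresh_px=cfg.gene_thresh_px,
            cb_thresh_px=cfg.cb_thresh_px,
        ),
        seed=cfg.seed,
    )
    io.write_spot_table_csv(
        imaging.cells_to_dataframe([c.table for c in cells]), out / "spots.csv"
    )

    tables["counts"].to_csv(out / "counts.tsv", sep="\t")
    tables["fpkm"].to_csv(out / "fpkm.tsv", sep="\t")
    tables["genes"].to_csv(out / "gene_meta.tsv", sep="\t")

    jmodel = synthetic.JunctionModel(
        genes=genes[: min(60, len(genes))],
        unannot_rate={"control": cfg.unannot_rate_control, "kd": cfg.unannot_rate_kd},
    )
    jtables = synthetic.simulate_junction_table(jmodel, ["control", "kd"], seed=cfg.seed)
    for cond, junctions in jtables.items():
        io.write_junctions_tsv(junctions, out / f"junctions_{cond}.tsv")
    annotated = sorted(synthetic.annotated_junction_set(jmodel))
    io.write_junctions_tsv(
        [splicing.Junction(*k, count=0) for k in annotated],
        out / "annotated_junctions.tsv",
    )
    for name in (
        "genes.bed",
        "genes.gtf",
        "spots.csv",
        "counts.tsv",
        "fpkm.tsv",
        "gene_meta.tsv",
        "junctions_control.tsv",
        "junctions_kd.tsv",
        "annotated_junctions.tsv",
    ):
        manifest[name] = cfg.config_hash


def _stage_fourc(cfg, out, genome, manifest):
    tracks = []
    for rep in (1, 2):
        reads = io.read_bed_reads(_require(out / f"reads_rep{rep}.bed", "fourc"))
        tracks.append(fourc.bin_reads(reads, genome, cfg.bin_size))
    profiles_rep = [
        {c: fourc.smooth_and_log(t[c], cfg.window, cfg.pseudocount) for c in t}
        for t in tracks
    ]
    r = fourc.genome_wide_correlation(*profiles_rep)
    pooled = {
        chrom: fourc.pool_replicates([t[chrom] for t in tracks])
        for chrom in tracks[0]
    }
    regions = []
    for chrom, track in sorted(pooled.items()):
        profile = fourc.smooth_and_log(track, cfg.window, cfg.pseudocount)
        io.write_bedgraph(profile, out / f"profile_{chrom}.bedgraph")
        manifest[f"profile_{chrom}.bedgraph"] = cfg.config_hash
        regions.extend(fourc.call_contact_regions(profile, cfg.threshold))
    io.write_bed_regions(regions, out / "contact_regions.bed")
    manifest["contact_regions.bed"] = cfg.config_hash
    report = {
        "replicate_correlation": r,
        "n_contact_regions": len(regions),
        "threshold": cfg.threshold,
    }
    _write_json(report, out / "fourc_report.json", cfg)
    manifest["fourc_report.json"] = cfg.config_hash
    return report


def _read_regions(path: Path) -> list[GenomicInterval]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append(GenomicInterval(chrom, int(start), int(end)))
    return regions


def _stage_genes(cfg, out, genome, arch, manifest):
    regions = _read_regions(_require(out / "contact_regions.bed", "genes"))
    genes = io.read_bed_genes(_require(out / "genes.bed", "genes"))
    # the viewpoint-proximal region is dominated by self-ligation signal in
    # any single-bait contact assay; exclude the called region containing
    # the bait from gene-set construction and the enrichment null
    bait_mid = arch.bait.midpoint
    regions = [
        r
        for r in regions
        if not (r.chrom == arch.bait.chrom and r.start <= bait_mid < r.end)
    ]
    extended = contact_genes.extend_regions(regions, cfg.extension_window, genome)
    positive = contact_genes.select_expressed_top_fraction(genes, extended)
    negative = contact_genes.define_negative_set(genes, regions)
    io.write_bed_genes(positive, out / "genes_4c_positive.bed")
    io.write_bed_genes(negative, out / "genes_4c_negative.bed")
    enrich = contact_genes.permutation_enrichment(
        regions,
        genes,
        genome,
        n_samples=cfg.n_permutation_samples,
        seed=cfg.seed,
    )
    report = {
        "n_4c_positive": len(positive),
        "n_4c_negative": len(negative),
        "observed_target_genes_near_contacts": enrich.observed,
        "null_mean": float(np.mean(enrich.null_counts)),
        "empirical_p": enrich.empirical_p,
        "n_samples": enrich.n_samples,
        "seed": enrich.seed,
    }
    _write_json(report, out / "enrichment.json", cfg)
    for name in ("genes_4c_positive.bed", "genes_4c_negative.bed", "enrichment.json"):
        manifest[name] = cfg.config_hash
    return report


def _stage_fish(cfg, out, manifest):
    df = io.read_spot_table_csv(_require(out / "spots.csv", "fish"))
    cells = imaging.cells_from_dataframe(df)
    events = imaging.classify_cells(
        cells, cfg.gene_thresh_px, cfg.cb_thresh_px
    )
    events.to_csv(out / "fish_events.csv", index=False)
    freq_dep, se_dep, n = imaging.interaction_frequency(
        cells, lambda label, bridging: label == "CB_dependent",
        cfg.gene_thresh_px, cfg.cb_thresh_px,
    )
    freq_indep, se_indep, _ = imaging.interaction_frequency(
        cells, lambda label, bridging: label == "CB_independent",
        cfg.gene_thresh_px, cfg.cb_thresh_px,
    )
    freq_bridge, se_bridge, _ = imaging.interaction_frequency(
        cells, lambda label, bridging: bridging,
        cfg.gene_thresh_px, cfg.cb_thresh_px,
    )
    report = {
        "n_eligible_cells": n,
        "cb_dependent_pct": freq_dep,
        "cb_dependent_se_pct": se_dep,
        "cb_independent_pct": freq_indep,
        "cb_independent_se_pct": se_indep,
        "bridging_pct": freq_bridge,
        "bridging_se_pct": se_bridge,
        "gene_thresh_um": imaging.px_to_um(cfg.gene_thresh_px, cfg.pixel_size_nm),
        "cb_thresh_um": imaging.px_to_um(cfg.cb_thresh_px, cfg.pixel_size_nm),
    }
    _write_json(report, out / "fish_frequencies.json", cfg)
    for name in ("fish_events.csv", "fish_frequencies.json"):
        manifest[name] = cfg.config_hash
    return report


def _stage_expr(cfg, out, manifest):
    fpkm = pd.read_csv(_require(out / "fpkm.tsv", "expr"), sep="\t", index_col=0)
    condition_map: dict[str, list[str]] = {}
    for col in fpkm.columns:
        cond = col.rsplit("_rep", 1)[0]
        condition_map.setdefault(cond, []).append(col)
    log2_table = expression.log2_average_replicates(
        fpkm, condition_map, cfg.log2_pseudocount
    )
    kd_conditions = [c for c in condition_map if c not in ("control_1", "control_2")]
    calls = expression.call_differential_table(
        log2_table, kd_conditions[0], lfc_threshold=cfg.lfc_threshold
    )
    calls.to_csv(out / "differential_calls.tsv", sep="\t")
    quartiles = expression.quartile_bins(log2_table["control_1"])
    quartiles.rename("quartile").to_csv(out / "quartiles.tsv", sep="\t")
    report = {
        "n_decreased": int((calls["direction"] == "decreased").sum()),
        "n_increased": int((calls["direction"] == "increased").sum()),
        "n_unchanged": int((calls["direction"] == "unchanged").sum()),
        "lfc_threshold": cfg.lfc_threshold,
        "log2_pseudocount": cfg.log2_pseudocount,
    }
    _write_json(report, out / "expression_report.json", cfg)
    for name in ("differential_calls.tsv", "quartiles.tsv", "expression_report.json"):
        manifest[name] = cfg.config_hash
    return report


def _stage_splice(cfg, out, manifest):
    control = io.read_junctions_tsv(_require(out / "junctions_control.tsv", "splice"))
    kd = io.read_junctions_tsv(_require(out / "junctions_kd.tsv", "splice"))
    annotated = {
        j.key
        for j in io.read_junctions_tsv(
            _require(out / "annotated_junctions.tsv", "splice")
        )
    }
    cls_control = splicing.classify_annotated(control, annotated)
    cls_kd = splicing.classify_annotated(kd, annotated)
    uniq_control, uniq_kd = splicing.unique_to_condition([control], [kd])
    unannot_keys_control = {
        j.key for j in control if j.key not in annotated
    }
    unannot_keys_kd = {j.key for j in kd if j.key not in annotated}
    summary_kd = splicing.per_gene_unannotated_summary(cls_kd)
    # genes with >=1 unannotated junction, control vs knockdown, as a 2x2
    genes_all = sorted({j.gene_id for j in control} | {j.gene_id for j in kd})
    per_gene_control = splicing.per_gene_unannotated_summary(cls_control)
    a = per_gene_control["n_genes_with_unannotated"]
    b = summary_kd["n_genes_with_unannotated"]
    n_genes = len(genes_all)
    p_fisher = splicing.fisher_2x2(
        [[a, n_genes - a], [b, n_genes - b]]
    )
    report = {
        "n_unique_control": len(uniq_control),
        "n_unique_kd": len(uniq_kd),
        "n_unannotated_control": len(unannot_keys_control),
        "n_unannotated_kd": len(unannot_keys_kd),
        "n_genes_with_unannotated_kd": b,
        "fraction_multiple_kd": summary_kd["fraction_with_multiple"],
        "fisher_p_genes_with_unannotated": p_fisher,
    }
    _write_json(report, out / "splicing_report.json", cfg)
    manifest["splicing_report.json"] = cfg.config_hash
    return report


def _stage_geometry(cfg, out, manifest):
    g = geometry.ProjectedGeometry(cfg.nuc_rad, cfg.ct_rad, cfg.delta)
    p_closed = geometry.expected_association_probability(g)
    p_mc, se = geometry.monte_carlo_association(g, cfg.mc_draws, seed=cfg.seed)
    report = {
        "expected_association_pct": 100 * p_closed,
        "monte_carlo_pct": 100 * p_mc,
        "monte_carlo_se_pct": 100 * se,
        "n_draws": cfg.mc_draws,
    }
    _write_json(report, out / "geometry_report.json", cfg)
    manifest["geometry_report.json"] = cfg.config_hash
    return report
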