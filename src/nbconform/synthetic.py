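"""Seeded synthetic-data generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here: a toy
genome with class-labelled gene annotation, 4C reads following a bait-
centred distance-decay model with planted cis/trans contact peaks, raw
barcoded FASTQ-style reads, per-cell FISH/IF spot tables with planted
CB-dependent and CB-independent gene-pairing rates (optionally rendered to
image stacks), log-normal expression tables with planted knockdown
effects, junction tables with planted unannotated-junction rates, and
pairwise splicing events with planted PSI.

The data being emulated carry no canonical distributional forms, so the
forms here (power-law contact decay floored at 1 kb, log-normal
expression, Poisson junction noise, Gaussian nuclear radii, uniform-in-
disc spot placement) are package design choices; each generator's
headline parameter is recoverable by its downstream analysis stage, which
is what the test suite pins down.

Each generator derives an independent RNG stream from its seed, so stages
are individually reproducible.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GENE_CLASSES, GeneRecord, GenomicInterval, ReadRecord, ToyGenome
from .imaging import CellSpotTable, Spot
from .splicing import Junction, JunctionKey, SplicingEvent

READ_LENGTH = 50
SEGMENT = 1_000  # bp resolution of the 4C density model (also the decay floor)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """One reproducible RNG stream per generator stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


def default_genome() -> ToyGenome:
    """Two-chromosome toy genome: a 4 Mb cis chromosome (carries the bait)
    and a 2 Mb trans chromosome."""
    return ToyGenome([("chr1", 4_000_000), ("chr2", 2_000_000)])


# ---------------------------------------------------------------- annotation


def generate_genome_annotation(
    genome: ToyGenome,
    class_mix: dict[str, float],
    n_genes: int = 200,
    gene_length_range: tuple[int, int] = (1_000, 5_000),
    seed: int = 0,
) -> list[GeneRecord]:
    """Non-overlapping genes with classes drawn from ``class_mix``.

    Genes are laid out in disjoint slots allocated to chromosomes in
    proportion to their lengths; expression is left at 0 (filled in by the
    expression generator or by the caller).
    """
    total = sum(class_mix.values())
    if not np.isclose(total, 1.0) or any(v < 0 for v in class_mix.values()):
        raise ValueError("class_mix proportions must be non-negative and sum to 1")
    unknown = set(class_mix) - set(GENE_CLASSES)
    if unknown:
        raise ValueError(f"unknown gene classes {sorted(unknown)}")
    rng = stage_rng(seed, "annotation")
    slot = gene_length_range[1] * 2
    slots: list[tuple[str, int]] = []
    for chrom, length in genome.chromosomes:
        slots.extend((chrom, s) for s in range(0, length - slot, slot))
    if n_genes > len(slots):
        raise ValueError(f"cannot place {n_genes} non-overlapping genes")
    chosen = rng.choice(len(slots), size=n_genes, replace=False)
    classes = rng.choice(
        list(class_mix), size=n_genes, p=np.array(list(class_mix.values())) / total
    )
    genes = []
    for i, (slot_idx, cls) in enumerate(zip(np.sort(chosen), classes)):
        chrom, base = slots[slot_idx]
        length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        start = base + int(rng.integers(0, slot - length))
        genes.append(
            GeneRecord(
                gene_id=f"G{i:05d}",
                interval=GenomicInterval(chrom, start, start + length),
                gene_class=str(cls),
            )
        )
    return genes


# ------------------------------------------------------------------- 4C reads


@dataclass
class PlantedArchitecture:
    """Planted 4C contact architecture around a bait.

    Cis read density follows ``background_rate * (d / 1 kb)^(-decay)`` with
    the bait distance d floored at 1 kb; trans density is uniform at
    ``background_rate * trans_level`` (the trans level is the far-contact
    background relative to the cis density at the floor distance). Peaks
    multiply the local density by their enrichment factor.
    """

    bait: GenomicInterval
    cis_peaks: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    trans_peaks: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    decay_exponent: float = 1.0
    background_rate: float = 1.0
    trans_level: float = 5e-4

    def validate(self, genome: ToyGenome) -> None:
        if self.decay_exponent < 0:
            raise ValueError("decay_exponent must be >= 0")
        if self.background_rate <= 0 or self.trans_level <= 0:
            raise ValueError("background rates must be > 0")
        if not genome.contains(self.bait):
            raise ValueError("bait outside genome")
        for iv, factor in self.cis_peaks + self.trans_peaks:
            if not genome.contains(iv):
                raise ValueError(f"peak {iv} outside genome")
            if not np.isfinite(factor) or factor < 1:
                raise ValueError("enrichment factors must be finite and >= 1")
        for iv, _ in self.cis_peaks:
            if iv.chrom != self.bait.chrom:
                raise ValueError("cis peaks must share the bait chromosome")
        for iv, _ in self.trans_peaks:
            if iv.chrom == self.bait.chrom:
                raise ValueError("trans peaks must not share the bait chromosome")


def default_architecture(genome: ToyGenome | None = None) -> PlantedArchitecture:
    """Bait at 1 Mb on chr1; two 50 kb cis peaks and one trans peak, all at
    50x enrichment."""
    genome = genome or default_genome()
    chrom = genome.names[0]
    return PlantedArchitecture(
        bait=GenomicInterval(chrom, 1_000_000, 1_010_000),
        cis_peaks=[
            (GenomicInterval(chrom, 2_000_000, 2_050_000), 50.0),
            (GenomicInterval(chrom, 3_200_000, 3_250_000), 50.0),
        ],
        trans_peaks=[(GenomicInterval(genome.names[1], 1_000_000, 1_050_000), 50.0)],
    )


def fourc_segment_weights(
    arch: PlantedArchitecture, genome: ToyGenome
) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Relative sampling weight of every 1 kb genome segment under the
    planted architecture (the generator's density model, exposed so tests
    can compare empirical counts with expectation)."""
    segments: list[tuple[str, int]] = []
    weights: list[float] = []
    bait_mid = arch.bait.midpoint
    for chrom, length in genome.chromosomes:
        n_seg = length // SEGMENT
        starts = np.arange(n_seg) * SEGMENT
        mids = starts + SEGMENT // 2
        if chrom == arch.bait.chrom:
            d = np.maximum(np.abs(mids - bait_mid), SEGMENT).astype(float)
            w = arch.background_rate * (d / SEGMENT) ** (-arch.decay_exponent)
            peaks = arch.cis_peaks
        else:
            w = np.full(n_seg, arch.background_rate * arch.trans_level)
            peaks = arch.trans_peaks
        for iv, factor in peaks:
            in_peak = (mids >= iv.start) & (mids < iv.end)
            w[in_peak] *= factor
        segments.extend((chrom, int(s)) for s in starts)
        weights.append(w)
    return segments, np.concatenate(weights)


def simulate_4c_reads(
    arch: PlantedArchitecture,
    genome: ToyGenome,
    n_reads: int,
    seed: int = 0,
    read_length: int = READ_LENGTH,
) -> list[ReadRecord]:
    """Emit exactly ``n_reads`` mapped reads from the planted density."""
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if not genome.chromosomes:
        raise ValueError("empty genome")
    arch.validate(genome)
    rng = stage_rng(seed, "4c_reads")
    segments, weights = fourc_segment_weights(arch, genome)
    counts = rng.multinomial(n_reads, weights / weights.sum())
    reads = []
    idx = 0
    for (chrom, seg_start), c in zip(segments, counts):
        if c == 0:
            continue
        chrom_len = genome.length_of(chrom)
        starts = seg_start + rng.integers(0, SEGMENT, size=c)
        for s in starts:
            start = int(min(s, chrom_len - read_length))
            reads.append(
                ReadRecord(
                    chrom=chrom,
                    start=start,
                    end=start + read_length,
                    strand="+" if rng.random() < 0.5 else "-",
                    name=f"r{idx:07d}",
                )
            )
            idx += 1
    return reads


# ------------------------------------------------------------------- raw FASTQ


def simulate_4c_fastq(
    barcode_map: dict[str, str],
    bait_primer: str,
    n_reads: int,
    insert_length: int = 80,
    invalid_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str, list[int]]], dict[str, int]]:
    """Raw barcoded reads for the preprocessing stage.

    Returns (records, planted per-sample assignment counts). A fraction of
    reads optionally carries a corrupt barcode (planted rejections, counted
    under key ``"__invalid__"``).
    """
    rng = stage_rng(seed, "4c_fastq")
    samples = sorted(barcode_map)
    truth = {s: 0 for s in samples}
    truth["__invalid__"] = 0
    bases = np.array(list("ACGT"))
    records = []
    for i in range(n_reads):
        insert = "".join(rng.choice(bases, size=insert_length))
        if rng.random() < invalid_fraction:
            seq = "N" * max(len(b) for b in barcode_map.values()) + bait_primer + insert
            truth["__invalid__"] += 1
        else:
            sample = samples[int(rng.integers(len(samples)))]
            seq = barcode_map[sample] + bait_primer + insert
            truth[sample] += 1
        quals = [int(q) for q in rng.integers(30, 41, size=len(seq))]
        records.append((f"read{i:06d}", seq, quals))
    return records, truth


# ------------------------------------------------------------------ cell spots


@dataclass
class CellPopulationModel:
    """Planted FISH cell-population model.

    A fraction ``p_dep`` of cells carries a CB-clustered RNU1-VGOI triplet
    (gene-gene distance <= 3 px, gene-CB distance <= 5 px); ``p_indep``
    carries a CB-distal gene pair (gene-gene <= 3 px, every CB > 5 px away);
    remaining cells have no gene pairing. Every cell has at least one CB
    (1 + capped-Poisson extras) so all cells are analysis-eligible.
    """

    n_cells: int = 500
    nucleus_radius: tuple[float, float] = (40.0, 4.0)  # mean, sd in px
    alleles_per_gene: int = 2
    cb_extra_mean: float = 1.5  # CBs per cell = 1 + min(Poisson(mean), cap)
    cb_extra_cap: int = 5
    p_dep: float = 0.3
    p_indep: float = 0.1
    pixel_size: float = 320.0  # nm per px
    gene_thresh_px: float = 3.0
    cb_thresh_px: float = 5.0
    margin_px: float = 0.5  # guard band kept clear of the thresholds

    def validate(self) -> None:
        if not (0 <= self.p_dep <= 1 and 0 <= self.p_indep <= 1):
            raise ValueError("p_dep and p_indep must be probabilities")
        if self.p_dep + self.p_indep > 1:
            raise ValueError("p_dep + p_indep must be <= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.nucleus_radius[0] < 4 * self.cb_thresh_px:
            raise ValueError("nucleus too small to host separated spots")


@dataclass
class SimulatedCell:
    table: CellSpotTable
    radius: float
    centre: tuple[float, float]  # (x, y)
    true_label: str  # dependent | independent | none


def _uniform_in_disc(rng, centre, radius, n=1) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = 2 * np.pi * rng.random(n)
    return np.column_stack(
        [centre[0] + r * np.cos(theta), centre[1] + r * np.sin(theta)]
    )


def simulate_cell_spots(
    model: CellPopulationModel, seed: int = 0, max_tries: int = 200
) -> list[SimulatedCell]:
    """Generate per-cell spot tables with planted pairing configurations.

    Placement is by rejection sampling inside the nuclear disc: planted
    pairs honour their distance constraints exactly, and background spots
    keep a guard band clear of the thresholds so a cell's planted label is
    also its downstream classification. A nucleus in which the constraints
    cannot be satisfied within ``max_tries`` draws is regenerated with a
    fresh radius (never silently accepted).
    """
    model.validate()
    rng = stage_rng(seed, "cell_spots")
    gene_t, cb_t, m = model.gene_thresh_px, model.cb_thresh_px, model.margin_px
    cells: list[SimulatedCell] = []
    labels = rng.choice(
        ["dependent", "independent", "none"],
        size=model.n_cells,
        p=[model.p_dep, model.p_indep, 1 - model.p_dep - model.p_indep],
    )
    for ci, label in enumerate(labels):
        for _attempt in range(max_tries):
            radius = max(
                4 * cb_t,
                rng.normal(model.nucleus_radius[0], model.nucleus_radius[1]),
            )
            centre = (radius + 5.0, radius + 5.0)
            cell = _generate_one_cell(
                rng, model, str(label), radius, centre, gene_t, cb_t, m, max_tries
            )
            if cell is not None:
                cells.append(
                    SimulatedCell(
                        table=CellSpotTable(cell_id=f"cell{ci:05d}", spots=cell),
                        radius=radius,
                        centre=centre,
                        true_label=str(label),
                    )
                )
                break
        else:
            raise RuntimeError(f"could not generate cell {ci} ({label})")
    return cells


def _generate_one_cell(
    rng, model, label, radius, centre, gene_t, cb_t, m, max_tries
) -> dict[str, list[Spot]] | None:
    inner = radius - (cb_t + 1.0)  # planted satellites stay inside the nucleus
    n_cb = 1 + min(int(rng.poisson(model.cb_extra_mean)), model.cb_extra_cap)
    cb_xy = _uniform_in_disc(rng, centre, inner, n_cb)
    rnu1_xy: list[np.ndarray] = []
    vgoi_xy: list[np.ndarray] = []

    if label == "dependent":
        anchor = cb_xy[int(rng.integers(n_cb))]
        d1 = rng.uniform(0.5, cb_t - 2 * m)
        a1 = rng.uniform(0, 2 * np.pi)
        r_spot = anchor + d1 * np.array([np.cos(a1), np.sin(a1)])
        d2 = rng.uniform(0.3, gene_t - m)
        a2 = rng.uniform(0, 2 * np.pi)
        v_spot = r_spot + d2 * np.array([np.cos(a2), np.sin(a2)])
        rnu1_xy.append(r_spot)
        vgoi_xy.append(v_spot)
    elif label == "independent":
        # the planted gene pair must clear EVERY CB by more than the threshold
        for _ in range(max_tries):
            cand = _uniform_in_disc(rng, centre, inner)[0]
            if np.all(np.linalg.norm(cb_xy - cand, axis=1) > cb_t + m):
                break
        else:
            return None
        d2 = rng.uniform(0.3, gene_t - m)
        a2 = rng.uniform(0, 2 * np.pi)
        rnu1_xy.append(cand)
        vgoi_xy.append(cand + d2 * np.array([np.cos(a2), np.sin(a2)]))

    # background alleles: no accidental gene pairing within the guard band
    def place_background(existing_partners: list[np.ndarray], n: int, avoid_cb: bool):
        placed = []
        for _ in range(n):
            for _ in range(max_tries):
                cand = _uniform_in_disc(rng, centre, radius - 1.0)[0]
                ok = all(
                    np.linalg.norm(cand - p) > gene_t + m
                    for p in existing_partners
                )
                if ok and avoid_cb:
                    ok = np.all(np.linalg.norm(cb_xy - cand, axis=1) > cb_t + m)
                if ok:
                    placed.append(cand)
                    break
            else:
                return None
        return placed

    n_bg_rnu1 = model.alleles_per_gene - len(rnu1_xy)
    n_bg_vgoi = model.alleles_per_gene - len(vgoi_xy)
    # background RNU1 must avoid all VGOI (planted + background); in
    # independent cells it must also stay clear of CBs so no CB-dependent
    # event can arise from a background allele pairing (none can, since
    # background alleles never pair, but the CB clearance keeps the cell's
    # planted label unambiguous for the per-spot table too)
    bg_vgoi = place_background(rnu1_xy, n_bg_vgoi, avoid_cb=False)
    if bg_vgoi is None:
        return None
    vgoi_all = vgoi_xy + bg_vgoi
    bg_rnu1 = place_background(vgoi_all, n_bg_rnu1, avoid_cb=False)
    if bg_rnu1 is None:
        return None
    rnu1_all = rnu1_xy + bg_rnu1

    def to_spots(channel, coords):
        return [
            Spot(channel=channel, x=float(p[0]), y=float(p[1]),
                 intensity=float(rng.uniform(0.8, 1.0)))
            for p in coords
        ]

    return {
        "RNU1": to_spots("RNU1", rnu1_all),
        "VGOI": to_spots("VGOI", vgoi_all),
        "CB": to_spots("CB", cb_xy),
    }


# ------------------------------------------------------------------ rendering


def render_cell(
    cell: SimulatedCell,
    shape: tuple[int, int] | None = None,
    spot_sigma: float = 1.0,
    spot_amplitude: float = 200.0,
    background: float = 10.0,
    poisson_noise: bool = True,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Render one cell to a dict of 2D channel images (DAPI + spot channels)
    with Gaussian spots and optional Poisson noise."""
    rng = stage_rng(seed, "render")
    if shape is None:
        side = int(np.ceil(2 * (cell.radius + 8)))
        shape = (side, side)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx, cy = cell.centre
    dapi = np.where(
        (xx - cx) ** 2 + (yy - cy) ** 2 <= cell.radius**2, 120.0, 2.0
    )
    images = {"DAPI": dapi}
    for channel in ("RNU1", "VGOI", "CB"):
        img = np.full(shape, background, dtype=float)
        for s in cell.table.channel(channel):
            img += (
                spot_amplitude
                * s.intensity
                * np.exp(-((xx - s.x) ** 2 + (yy - s.y) ** 2) / (2 * spot_sigma**2))
            )
        images[channel] = img
    if poisson_noise:
        images = {k: rng.poisson(v).astype(float) for k, v in images.items()}
    return images


def simulate_nuclei_field(
    shape: tuple[int, int] = (256, 256),
    n_nuclei: int = 5,
    radius_range: tuple[float, float] = (18.0, 26.0),
    allow_border: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, int, int]:
    """A nuclear-stain field of disc nuclei, some possibly cut by the image
    border. Returns (image, n_planted, n_non_border)."""
    rng = stage_rng(seed, "nuclei_field")
    img = np.full(shape, 2.0)
    n_non_border = 0
    placed: list[tuple[float, float, float]] = []
    for _ in range(n_nuclei):
        for _ in range(500):
            r = rng.uniform(*radius_range)
            if allow_border:
                cx = rng.uniform(0, shape[1])
                cy = rng.uniform(0, shape[0])
            else:
                cx = rng.uniform(r + 2, shape[1] - r - 2)
                cy = rng.uniform(r + 2, shape[0] - r - 2)
            if all(
                np.hypot(cx - px, cy - py) > r + pr + 2 for px, py, pr in placed
            ):
                placed.append((cx, cy, r))
                break
        else:
            break
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cx, cy, r in placed:
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        img[disc] = 120.0
        # truth from the rasterized disc, matching what a segmenter sees
        touches = (
            disc[0, :].any() or disc[-1, :].any()
            or disc[:, 0].any() or disc[:, -1].any()
        )
        if disc.any() and not touches:
            n_non_border += 1
    return img, len(placed), n_non_border


# ------------------------------------------------------------------ expression


@dataclass
class ExpressionModel:
    """Log-normal expression with planted knockdown effects.

    ``baseline`` maps gene class -> (log2 location, log2 scale); knockdown
    conditions shift CB-proximal genes by ``kd_effect`` log2 units;
    replicates add independent N(0, replicate_noise) on the log2 scale.
    """

    n_genes: int = 1000
    baseline: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {cls: (3.0, 4.5) for cls in GENE_CLASSES}
    )
    kd_effect: float = -2.0
    replicate_noise: float = 0.5
    n_replicates: int = 2
    frac_cb_proximal: float = 0.1
    gene_length: int = 1_000
    mapped_total: int = 10_000_000

    def validate(self) -> None:
        if self.replicate_noise < 0:
            raise ValueError("replicate_noise must be >= 0")
        if any(s < 0 for _, s in self.baseline.values()):
            raise ValueError("baseline scales must be >= 0")
        if not 0 <= self.frac_cb_proximal <= 1:
            raise ValueError("frac_cb_proximal must be a probability")


def simulate_expression_table(
    model: ExpressionModel,
    conditions: list[str] = ("control_1", "control_2", "kd"),
    seed: int = 0,
    genes: list[GeneRecord] | None = None,
) -> dict:
    """Counts + FPKM tables over replicated conditions.

    Conditions named ``control_1`` and ``control_2`` are required;
    every other condition is treated as a knockdown and receives the
    planted ``kd_effect`` on CB-proximal genes. Returns a dict with the
    count and FPKM DataFrames (genes x samples), gene metadata (class and
    the planted ``cb_proximal`` flag), the condition -> samples map, and
    per-sample mapped totals.
    """
    model.validate()
    conditions = list(conditions)
    if len(conditions) < 2 or not {"control_1", "control_2"} <= set(conditions):
        raise ValueError("need >= 2 conditions including control_1 and control_2")
    rng = stage_rng(seed, "expression")
    if genes is not None:
        classes = [g.gene_class for g in genes]
        ids = [g.gene_id for g in genes]
    else:
        classes = list(
            rng.choice(
                ["snRNA", "snoRNA", "scaRNA", "histone", "coding"],
                size=model.n_genes,
                p=[0.05, 0.1, 0.05, 0.05, 0.75],
            )
        )
        ids = [f"G{i:05d}" for i in range(model.n_genes)]
    n = len(ids)
    base = np.array(
        [rng.normal(*model.baseline.get(c, (3.0, 4.5))) for c in classes]
    )
    cb_proximal = rng.random(n) < model.frac_cb_proximal
    condition_map: dict[str, list[str]] = {}
    fpkm_cols = {}
    for cond in conditions:
        shift = 0.0 if cond in ("control_1", "control_2") else model.kd_effect
        samples = [f"{cond}_rep{r + 1}" for r in range(model.n_replicates)]
        condition_map[cond] = samples
        for s in samples:
            log2_fpkm = (
                base
                + np.where(cb_proximal, shift, 0.0)
                + rng.normal(0, model.replicate_noise, size=n)
            )
            fpkm_cols[s] = 2.0**log2_fpkm
    fpkm = pd.DataFrame(fpkm_cols, index=ids)
    lengths = pd.Series(model.gene_length, index=ids, dtype=float)
    totals = pd.Series(model.mapped_total, index=fpkm.columns, dtype=float)
    counts = (
        fpkm.mul(lengths / 1e3, axis=0).mul(totals / 1e6, axis=1).round().astype(int)
    )
    meta = pd.DataFrame(
        {"gene_class": classes, "cb_proximal": cb_proximal}, index=ids
    )
    return {
        "counts": counts,
        "fpkm": fpkm,
        "genes": meta,
        "condition_map": condition_map,
        "gene_lengths": lengths,
        "mapped_totals": totals,
    }


# ------------------------------------------------------------------- junctions


@dataclass
class JunctionModel:
    """Planted junction tables: fixed annotated junctions per gene plus
    Poisson-distributed unannotated (noise) junctions per gene per condition.

    ``unannot_rate`` maps condition -> expected unannotated junctions per
    gene; annotated-junction read counts are Poisson with mean
    ``fpkm_link`` x the gene's relative expression x depth (in millions).
    """

    genes: list[GeneRecord]
    annotated_per_gene: int = 3
    unannot_rate: dict[str, float] = field(
        default_factory=lambda: {"control": 0.1, "kd": 0.2}
    )
    depth: float = 10.0  # millions of mapped reads per sample
    fpkm_link: float = 2.0
    unannot_count_mean: float = 3.0

    def validate(self) -> None:
        if not self.genes:
            raise ValueError("need at least one gene")
        if self.annotated_per_gene < 1:
            raise ValueError("annotated set must be non-empty")
        if any(r < 0 for r in self.unannot_rate.values()):
            raise ValueError("unannotated rates must be >= 0")


def annotated_junction_set(model: JunctionModel) -> set[JunctionKey]:
    """The planted reference annotation: evenly spaced junctions per gene."""
    keys: set[JunctionKey] = set()
    for g in model.genes:
        iv = g.interval
        step = max(iv.length // (model.annotated_per_gene + 1), 2)
        for k in range(model.annotated_per_gene):
            donor = iv.start + (k + 1) * step
            acceptor = min(donor + step // 2 + 1, iv.end - 1)
            if donor < acceptor:
                keys.add((iv.chrom, donor, acceptor, iv.strand))
    return keys


def simulate_junction_table(
    model: JunctionModel,
    conditions: list[str] = ("control", "kd"),
    seed: int = 0,
) -> dict[str, list[Junction]]:
    """One junction table per condition with planted unannotated noise.

    Annotated junctions appear in every condition with Poisson counts;
    unannotated junctions are drawn per gene per condition at that
    condition's rate, at coordinates inside the gene that never collide
    with the annotated set.
    """
    model.validate()
    rng = stage_rng(seed, "junctions")
    annotated = annotated_junction_set(model)
    by_gene_annot: dict[str, list[JunctionKey]] = {g.gene_id: [] for g in model.genes}
    for g in model.genes:
        by_gene_annot[g.gene_id] = sorted(
            k for k in annotated
            if k[0] == g.interval.chrom
            and g.interval.start <= k[1]
            and k[2] <= g.interval.end
        )
    tables: dict[str, list[Junction]] = {}
    for cond in conditions:
        rate = model.unannot_rate.get(cond, 0.0)
        rows: list[Junction] = []
        for g in model.genes:
            iv = g.interval
            mean_cov = model.fpkm_link * model.depth
            for key in by_gene_annot[g.gene_id]:
                count = int(rng.poisson(mean_cov))
                rows.append(Junction(*key, count=count, gene_id=g.gene_id))
            n_noise = int(rng.poisson(rate))
            for _ in range(n_noise):
                for _ in range(100):
                    donor = int(rng.integers(iv.start, iv.end - 2))
                    acceptor = int(rng.integers(donor + 1, iv.end))
                    key = (iv.chrom, donor, acceptor, iv.strand)
                    if key not in annotated:
                        break
                count = 1 + int(rng.poisson(model.unannot_count_mean))
                rows.append(Junction(*key, count=count, gene_id=g.gene_id))
        tables[cond] = rows
    return tables


# -------------------------------------------------------------- splicing events


def simulate_splicing_events(
    psi_by_condition: dict[str, float],
    depth: int = 200,
    n_events: int = 1,
    gene_prefix: str = "E",
    seed: int = 0,
) -> dict[str, list[SplicingEvent]]:
    """Pairwise inclusion/exclusion events with planted PSI per condition:
    inclusion ~ Binomial(depth, PSI), exclusion = depth - inclusion."""
    for cond, p in psi_by_condition.items():
        if not 0 <= p <= 1:
            raise ValueError(f"PSI for {cond!r} must be in [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = stage_rng(seed, "splicing_events")
    out: dict[str, list[SplicingEvent]] = {}
    for cond, p in psi_by_condition.items():
        events = []
        for i in range(n_events):
            inc = int(rng.binomial(depth, p))
            events.append(
                SplicingEvent(gene_id=f"{gene_prefix}{i:04d}", inclusion=inc,
                              exclusion=depth - inc)
            )
        out[cond] = events
    return out
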