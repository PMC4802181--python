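"""Contact-gene set construction and permutation enrichment.

From called 4C contact regions: extend regions symmetrically (±10/25/50 kb),
intersect with genes by the midpoint rule, filter to highly expressed genes
(top 5% genome-wide) to get the 4C-positive set, define a distance-matched
4C-negative control set, and test gene-class enrichment near contacts with
a random-interval permutation null.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import (
    GeneRecord,
    GenomicInterval,
    ToyGenome,
    merge_intervals,
    min_distance_to_set,
    point_in_intervals,
    random_nonoverlapping_intervals,
)

DEFAULT_TARGET_CLASSES = frozenset({"snRNA", "snoRNA", "scaRNA", "histone"})
DEFAULT_PROXIMITY = 10_000
DEFAULT_N_SAMPLES = 100


@dataclass
class EnrichmentResult:
    """Observed count vs a permutation null of random matched intervals."""

    observed: int
    null_counts: list[int]
    empirical_p: float
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.null_counts)


def extend_regions(
    regions: list[GenomicInterval],
    window: int,
    genome: ToyGenome,
) -> list[GenomicInterval]:
    """Grow each region by ``window`` bp on both sides, clip to chromosome
    bounds and merge overlapping results."""
    if window < 0:
        raise ValueError("window must be >= 0")
    extended = [
        GenomicInterval(
            r.chrom,
            max(0, r.start - window),
            min(genome.length_of(r.chrom), r.end + window),
        )
        for r in regions
    ]
    return merge_intervals(extended) if extended else []


def intersect_genes_midpoint(
    genes: list[GeneRecord],
    regions: list[GenomicInterval],
    min_overlap_fraction: float | None = None,
) -> list[GeneRecord]:
    """Genes whose midpoint falls inside any region (the primary rule).

    ``min_overlap_fraction`` switches to an intersectBed-style rule: the
    gene is kept if at least that fraction of its length overlaps a region.
    """
    if min_overlap_fraction is None:
        return [
            g
            for g in genes
            if point_in_intervals(g.interval.chrom, g.interval.midpoint, regions)
        ]
    kept = []
    for g in genes:
        overlap = sum(
            min(g.interval.end, r.end) - max(g.interval.start, r.start)
            for r in regions
            if g.interval.overlaps(r)
        )
        if overlap >= min_overlap_fraction * g.interval.length:
            kept.append(g)
    return kept


def expression_threshold(genes: list[GeneRecord], fraction: float = 0.05) -> float:
    """Nearest-rank (1 - fraction) quantile of expression over all genes."""
    if not genes:
        raise ValueError("empty gene list")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    values = np.sort([g.expression for g in genes])
    n = len(values)
    # nearest-rank: smallest value with at least ceil((1-fraction)*n) values <= it
    rank = int(np.ceil((1 - fraction) * n))
    rank = min(max(rank, 0), n - 1)
    return float(values[rank])


def select_expressed_top_fraction(
    genes: list[GeneRecord],
    regions: list[GenomicInterval],
    fraction: float = 0.05,
) -> list[GeneRecord]:
    """4C-positive candidates: midpoint-overlapping genes whose expression is
    in the top ``fraction`` of ALL genes (ties at the threshold kept)."""
    thresh = expression_threshold(genes, fraction)
    overlapping = intersect_genes_midpoint(genes, regions)
    return [g for g in overlapping if g.expression >= thresh]


def define_negative_set(
    genes: list[GeneRecord],
    regions: list[GenomicInterval],
    distance: int = 50_000,
    fraction: float = 0.05,
) -> list[GeneRecord]:
    """4C-negative controls: top-fraction expressed genes residing more than
    ``distance`` bp from every contact region."""
    thresh = expression_threshold(genes, fraction)
    return [
        g
        for g in genes
        if g.expression >= thresh
        and min_distance_to_set(g.interval, regions) > distance
    ]


def count_near_regions(
    genes: list[GeneRecord],
    regions: list[GenomicInterval],
    classes: frozenset[str] | set[str],
    proximity: int = DEFAULT_PROXIMITY,
) -> int:
    """Number of target-class genes within ``proximity`` bp of any region."""
    return sum(
        1
        for g in genes
        if g.gene_class in classes
        and min_distance_to_set(g.interval, regions) <= proximity
    )


class _TargetGeneArrays:
    """Vectorized gene coordinates for fast repeated proximity counting."""

    def __init__(self, genes: list[GeneRecord], classes) -> None:
        targets = [g for g in genes if g.gene_class in classes]
        self.chroms = np.array([g.interval.chrom for g in targets])
        self.starts = np.array([g.interval.start for g in targets], dtype=float)
        self.ends = np.array([g.interval.end for g in targets], dtype=float)

    def count_near(self, regions: list[GenomicInterval], proximity: int) -> int:
        if len(self.starts) == 0 or not regions:
            return 0
        near = np.zeros(len(self.starts), dtype=bool)
        for r in regions:
            on_chrom = self.chroms == r.chrom
            gap = np.maximum(
                np.maximum(self.starts - r.end, r.start - self.ends), 0.0
            )
            near |= on_chrom & (gap <= proximity)
        return int(near.sum())


def permutation_enrichment(
    regions: list[GenomicInterval],
    genes: list[GeneRecord],
    genome: ToyGenome,
    target_classes: frozenset[str] | set[str] = DEFAULT_TARGET_CLASSES,
    proximity: int = DEFAULT_PROXIMITY,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    genome_wide_placement: bool = False,
) -> EnrichmentResult:
    """Empirical enrichment of target-class genes near contact regions.

    Each null sample consists of random intervals matching the observed
    regions in count and length — placed on the same chromosomes by default,
    or anywhere in the genome with ``genome_wide_placement`` — without
    overlap among themselves. The empirical p uses the +1 correction,
    ``(1 + #{null >= observed}) / (1 + n_samples)``, so its minimum is
    1/(n_samples+1), never 0.
    """
    if not regions:
        raise ValueError("no contact regions supplied")
    rng = np.random.default_rng(seed)
    targets = _TargetGeneArrays(genes, target_classes)
    observed = targets.count_near(regions, proximity)
    lengths_total = genome.total_length
    null_counts: list[int] = []
    for _ in range(n_samples):
        if genome_wide_placement:
            lengths_by_chrom = []
            probs = np.array(
                [length for _, length in genome.chromosomes], dtype=float
            )
            probs /= lengths_total
            for r in regions:
                chrom = genome.names[int(rng.choice(len(probs), p=probs))]
                lengths_by_chrom.append((chrom, r.length))
        else:
            lengths_by_chrom = [(r.chrom, r.length) for r in regions]
        sample = random_nonoverlapping_intervals(lengths_by_chrom, genome, rng)
        null_counts.append(targets.count_near(sample, proximity))
    empirical_p = (1 + sum(c >= observed for c in null_counts)) / (1 + n_samples)
    return EnrichmentResult(
        observed=observed,
        null_counts=null_counts,
        empirical_p=float(empirical_p),
        seed=seed,
    )
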