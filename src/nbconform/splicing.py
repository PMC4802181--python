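"""Splice-junction noise quantification.

Junctions are keyed by (chrom, donor, acceptor, strand) and flagged
annotated/unannotated by exact lookup against a reference set. Condition-
unique junction sets, per-gene unannotated tallies, depth-/expression-
normalized detection metrics, PSI (percent spliced in) with delta-PSI, and
a two-sided Fisher exact test complete the noise analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneRecord

JunctionKey = tuple[str, int, int, str]

JUNCTION_COLUMNS = ["chrom", "donor", "acceptor", "strand", "count", "gene_id"]


@dataclass(frozen=True)
class Junction:
    chrom: str
    donor: int
    acceptor: int
    strand: str
    count: int
    gene_id: str = "."

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError(
                f"junction {self.chrom}:{self.donor}-{self.acceptor}: "
                "donor must be < acceptor"
            )
        if self.count < 0:
            raise ValueError("junction count must be >= 0")

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.donor, self.acceptor, self.strand)


@dataclass(frozen=True)
class SplicingEvent:
    """A pairwise inclusion/exclusion event for one gene."""

    gene_id: str
    inclusion: int
    exclusion: int

    def __post_init__(self) -> None:
        if self.inclusion < 0 or self.exclusion < 0:
            raise ValueError("event counts must be >= 0")


@dataclass(frozen=True)
class NoiseMetrics:
    """Depth- and expression-normalized junction detection metrics.

    reads_per_million = coverage / millions of reads (knockdown);
    expected_at_depth = wild-type depth (millions) * reads_per_million;
    reads_per_fpkm = coverage / knockdown FPKM;
    expected_at_fpkm = wild-type FPKM * reads_per_fpkm.
    Undefined ratios (zero denominator) are NaN, never silent zeros.
    """

    coverage: float
    reads_per_million: float
    expected_at_depth: float
    reads_per_fpkm: float
    expected_at_fpkm: float


def classify_annotated(
    junctions: list[Junction], annotation: set[JunctionKey]
) -> pd.DataFrame:
    """Exact-match annotation lookup: a 1-bp shift in donor or acceptor makes
    a junction unannotated."""
    rows = []
    for j in junctions:
        rows.append(
            {
                "chrom": j.chrom,
                "donor": j.donor,
                "acceptor": j.acceptor,
                "strand": j.strand,
                "count": j.count,
                "gene_id": j.gene_id,
                "annotated": j.key in annotation,
            }
        )
    df = pd.DataFrame(rows, columns=JUNCTION_COLUMNS + ["annotated"])
    return df.astype({"annotated": bool})


def detected_keys(
    tables: list[list[Junction]],
    min_count: int = 1,
    require_all_members: bool = False,
) -> set[JunctionKey]:
    """Junction keys detected (count >= min_count) in a condition group:
    in any member by default, or in every member with
    ``require_all_members``."""
    per_member = [
        {j.key for j in table if j.count >= min_count} for table in tables
    ]
    if not per_member:
        return set()
    return (
        set.intersection(*per_member)
        if require_all_members
        else set.union(*per_member)
    )


def unique_to_condition(
    group_a: list[list[Junction]],
    group_b: list[list[Junction]],
    min_count: int = 1,
    require_all_members: bool = False,
) -> tuple[set[JunctionKey], set[JunctionKey]]:
    """Junction keys unique to each of two condition groups.

    Returns (unique to A, unique to B): detected in >=1 member of the group
    and in NO member of the other group. The two sets are disjoint by
    construction.
    """
    det_a = detected_keys(group_a, min_count, require_all_members)
    det_b = detected_keys(group_b, min_count, require_all_members)
    # absence from the other group is always "not detected in any member"
    any_a = detected_keys(group_a, min_count, False)
    any_b = detected_keys(group_b, min_count, False)
    return det_a - any_b, det_b - any_a


def assign_junctions_to_genes(
    junctions: list[Junction], genes: list[GeneRecord]
) -> list[Junction]:
    """Assign each junction to the gene fully containing it (donor and
    acceptor both inside the gene interval, same chromosome).

    Junctions contained in no gene get gene_id "intergenic"; junctions
    contained in more than one gene get "ambiguous".
    """
    out = []
    for j in junctions:
        hosts = [
            g.gene_id
            for g in genes
            if g.interval.chrom == j.chrom
            and g.interval.start <= j.donor
            and j.acceptor <= g.interval.end
        ]
        if len(hosts) == 1:
            gene_id = hosts[0]
        elif not hosts:
            gene_id = "intergenic"
        else:
            gene_id = "ambiguous"
        out.append(
            Junction(j.chrom, j.donor, j.acceptor, j.strand, j.count, gene_id)
        )
    return out


def per_gene_unannotated_summary(classified: pd.DataFrame) -> dict:
    """Per-gene unannotated-junction tallies.

    Expects the output of :func:`classify_annotated` with gene assignments.
    Returns per-gene counts, the number of genes with >=1 unannotated
    junction, and the fraction of those genes with more than one.
    """
    unannot = classified[~classified["annotated"]]
    genic = unannot[~unannot["gene_id"].isin(["intergenic", "ambiguous"])]
    per_gene = genic.groupby("gene_id").size().sort_index()
    n_genes = int((per_gene >= 1).sum())
    n_multi = int((per_gene > 1).sum())
    return {
        "per_gene_counts": per_gene,
        "n_genes_with_unannotated": n_genes,
        "fraction_with_multiple": (n_multi / n_genes) if n_genes else float("nan"),
        "n_intergenic": int((unannot["gene_id"] == "intergenic").sum()),
        "n_ambiguous": int((unannot["gene_id"] == "ambiguous").sum()),
    }


def normalization_metrics(
    coverage: float,
    millions_of_reads_kd: float,
    millions_of_reads_wt: float,
    fpkm_kd: float,
    fpkm_wt: float,
) -> NoiseMetrics:
    """The four printed-formula metrics; zero denominators yield NaN."""
    if millions_of_reads_kd <= 0 or millions_of_reads_wt <= 0:
        raise ValueError("sequencing depths must be > 0")
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    rpm = coverage / millions_of_reads_kd
    expected_depth = millions_of_reads_wt * rpm
    if fpkm_kd > 0:
        rpf = coverage / fpkm_kd
        expected_fpkm = fpkm_wt * rpf
    else:
        rpf = float("nan")
        expected_fpkm = float("nan")
    return NoiseMetrics(
        coverage=float(coverage),
        reads_per_million=float(rpm),
        expected_at_depth=float(expected_depth),
        reads_per_fpkm=float(rpf),
        expected_at_fpkm=float(expected_fpkm),
    )


def psi(event: SplicingEvent) -> float:
    """Percent spliced in: inclusion / (inclusion + exclusion); NaN for 0/0."""
    total = event.inclusion + event.exclusion
    if total == 0:
        return float("nan")
    return event.inclusion / total


def delta_psi(a: SplicingEvent, b: SplicingEvent) -> float:
    """PSI(b) - PSI(a); undefined (NaN) propagates from either side."""
    pa, pb = psi(a), psi(b)
    if math.isnan(pa) or math.isnan(pb):
        return float("nan")
    return pb - pa


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (probability-mass
    definition: sum of tables at least as extreme as observed)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if t.sum(axis=0).min() == 0 and t.sum(axis=1).min() == 0:
        raise ValueError("degenerate table: an all-zero margin")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
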