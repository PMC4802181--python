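"""Core genomic domain types and interval arithmetic.

All coordinates are 0-based half-open internally; conversion to other
conventions (GTF-style 1-based inclusive) happens only at format
boundaries in :mod:`nbconform.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GENE_CLASSES = ("snRNA", "snoRNA", "scaRNA", "histone", "coding", "other")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # floor of (start+end)/2, the convention used for midpoint-overlap
        return (self.start + self.end) // 2

    def distance_to(self, other: "GenomicInterval") -> float:
        """Edge-to-edge distance in bp; 0 if overlapping; inf across chromosomes."""
        if self.chrom != other.chrom:
            return float("inf")
        if self.start < other.end and other.start < self.end:
            return 0.0
        return float(max(self.start, other.start) - min(self.end, other.end))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its class label and reference-condition expression."""

    gene_id: str
    interval: GenomicInterval
    gene_class: str
    expression: float = 0.0

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if self.expression < 0:
            raise ValueError("expression must be >= 0")


@dataclass(frozen=True)
class ReadRecord:
    """A mapped read as a genomic interval (BED6-compatible)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid read {self.name}: [{self.start}, {self.end})")


@dataclass
class ToyGenome:
    """A small genome: ordered chromosomes with lengths in bp."""

    chromosomes: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def contains(self, iv: GenomicInterval) -> bool:
        try:
            return iv.end <= self.length_of(iv.chrom)
        except KeyError:
            return False

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals; result sorted by (chrom, start)."""
    merged: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def min_distance_to_set(
    iv: GenomicInterval, intervals: list[GenomicInterval]
) -> float:
    """Minimum edge-to-edge distance from ``iv`` to any interval in the set."""
    if not intervals:
        return float("inf")
    return min(iv.distance_to(other) for other in intervals)


def point_in_intervals(chrom: str, pos: int, intervals: list[GenomicInterval]) -> bool:
    return any(
        iv.chrom == chrom and iv.start <= pos < iv.end for iv in intervals
    )


def random_nonoverlapping_intervals(
    lengths_by_chrom: list[tuple[str, int]],
    genome: ToyGenome,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> list[GenomicInterval]:
    """Place intervals of the given lengths uniformly on their chromosomes,
    rejecting overlaps among the placed set.

    Used as the null model for permutation enrichment: each null sample
    matches the observed regions in count, length and chromosome.
    """
    placed: list[GenomicInterval] = []
    for chrom, length in lengths_by_chrom:
        chrom_len = genome.length_of(chrom)
        if length > chrom_len:
            raise ValueError(
                f"interval of length {length} does not fit on {chrom} ({chrom_len} bp)"
            )
        for _ in range(max_tries):
            start = int(rng.integers(0, chrom_len - length + 1))
            cand = GenomicInterval(chrom, start, start + length)
            if not any(cand.overlaps(p) for p in placed):
                placed.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place non-overlapping interval of length {length} on {chrom}"
            )
    return placed
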