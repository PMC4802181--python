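"""4C-seq contact profiling.

The processing chain mirrors standard single-viewpoint chromosome
conformation capture practice: raw reads are demultiplexed, bait-trimmed
and quality filtered; mapped reads are counted into non-overlapping 10 kb
bins; replicate tracks are pooled; the pooled track is smoothed with a
running 100 kb window, a 0.1 pseudocount is added and the signal is taken
to log2; contact regions are maximal runs of bins whose smoothed log2
signal exceeds a threshold (default >7).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomicInterval, ReadRecord, ToyGenome

DEFAULT_BIN_SIZE = 10_000
DEFAULT_WINDOW = 100_000
DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_THRESHOLD = 7.0
DEFAULT_TRIM_LEN = 50


@dataclass
class BinnedTrack:
    """Per-chromosome read counts in non-overlapping fixed-size bins."""

    chrom: str
    bin_size: int
    counts: np.ndarray  # int, length = ceil(chrom_length / bin_size)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("bin counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_centres(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_size


@dataclass
class SmoothedProfile:
    """Running-window-averaged, pseudocounted, log2-scale 4C signal."""

    chrom: str
    bin_size: int
    values: np.ndarray  # float, log2 scale
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("smoothed values must be finite")


@dataclass
class ContactRegion:
    """A maximal run of above-threshold bins, as a genomic interval."""

    interval: GenomicInterval
    peak_value: float
    threshold: float


@dataclass
class RejectedRead:
    read_id: str
    reason: str  # too_short | no_barcode | no_bait | low_quality


@dataclass
class PreprocessResult:
    """Demultiplexed, trimmed reads per sample plus a rejection log."""

    by_sample: dict[str, list[tuple[str, str, list[int]]]]  # id, seq, quals
    rejected: list[RejectedRead] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return sum(len(v) for v in self.by_sample.values())


def preprocess_reads(
    records: list[tuple[str, str, list[int]]],
    barcode_map: dict[str, str],
    bait_primer: str,
    trim_len: int = DEFAULT_TRIM_LEN,
    min_mean_quality: float = 20.0,
) -> PreprocessResult:
    """Demultiplex, bait-trim and quality-filter raw reads.

    Parameters
    ----------
    records
        (read_id, sequence, phred_qualities) tuples, e.g. from FASTQ.
    barcode_map
        sample name -> barcode sequence. Barcodes must be prefix-free so
        every read matches at most one sample.
    bait_primer
        The viewpoint primer expected immediately after the barcode; it is
        stripped along with the barcode.
    trim_len
        Surviving reads are truncated to their first ``trim_len`` nt.
    min_mean_quality
        Reads with mean phred quality below this (after trimming) are
        rejected with reason ``low_quality``.
    """
    if not bait_primer:
        raise ValueError("bait primer must be non-empty")
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcodes must be unique")
    for a in barcodes:
        for b in barcodes:
            if a != b and b.startswith(a):
                raise ValueError(f"barcode set not prefix-free: {a!r} prefixes {b!r}")

    by_sample: dict[str, list[tuple[str, str, list[int]]]] = {
        s: [] for s in barcode_map
    }
    rejected: list[RejectedRead] = []
    for read_id, seq, quals in records:
        sample = next(
            (s for s, bc in barcode_map.items() if seq.startswith(bc)), None
        )
        if sample is None:
            min_prefix = min(len(bc) for bc in barcodes) + len(bait_primer)
            reason = "too_short" if len(seq) < min_prefix else "no_barcode"
            rejected.append(RejectedRead(read_id, reason))
            continue
        bc = barcode_map[sample]
        rest, rest_q = seq[len(bc):], quals[len(bc):]
        if len(rest) < len(bait_primer):
            rejected.append(RejectedRead(read_id, "too_short"))
            continue
        if not rest.startswith(bait_primer):
            rejected.append(RejectedRead(read_id, "no_bait"))
            continue
        trimmed = rest[len(bait_primer):][:trim_len]
        trimmed_q = rest_q[len(bait_primer):][:trim_len]
        if not trimmed:
            rejected.append(RejectedRead(read_id, "too_short"))
            continue
        if np.mean(trimmed_q) < min_mean_quality:
            rejected.append(RejectedRead(read_id, "low_quality"))
            continue
        by_sample[sample].append((read_id, trimmed, trimmed_q))
    return PreprocessResult(by_sample=by_sample, rejected=rejected)


def bin_reads(
    reads: list[ReadRecord],
    genome: ToyGenome,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> dict[str, BinnedTrack]:
    """Count reads into non-overlapping bins; a read increments every bin
    it overlaps, so a boundary-spanning read is counted in both bins."""
    tracks = {
        chrom: np.zeros(-(-length // bin_size), dtype=np.int64)
        for chrom, length in genome.chromosomes
    }
    for read in reads:
        if read.chrom not in tracks or read.end > genome.length_of(read.chrom):
            raise ValueError(
                f"read {read.name} {read.chrom}:{read.start}-{read.end} "
                "lies outside the genome"
            )
        first = read.start // bin_size
        last = (read.end - 1) // bin_size
        tracks[read.chrom][first : last + 1] += 1
    return {
        chrom: BinnedTrack(chrom=chrom, bin_size=bin_size, counts=counts)
        for chrom, counts in tracks.items()
    }


def pool_replicates(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Element-wise sum of replicate tracks (pooling reads)."""
    if not tracks:
        raise ValueError("no tracks to pool")
    first = tracks[0]
    for t in tracks[1:]:
        if (
            t.chrom != first.chrom
            or t.bin_size != first.bin_size
            or t.n_bins != first.n_bins
        ):
            raise ValueError("replicate tracks must share chromosome, bin size, shape")
    return BinnedTrack(
        chrom=first.chrom,
        bin_size=first.bin_size,
        counts=np.sum([t.counts for t in tracks], axis=0),
    )


def smooth_and_log(
    track: BinnedTrack,
    window: int = DEFAULT_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> SmoothedProfile:
    """Running window-average assigned to each bin centre, then log2 with a
    pseudocount.

    The window is realized as "bin centres within ±window/2 of this bin's
    centre": with 10 kb bins and a 100 kb window that is 11 bins in the
    interior. Chromosome ends use the truncated window (the mean runs over
    however many bins actually fall inside).
    """
    if window < track.bin_size:
        raise ValueError("window must be at least one bin")
    half_bins = int(window / 2 // track.bin_size)
    counts = track.counts.astype(float)
    n = len(counts)
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    idx = np.arange(n)
    lo = np.maximum(idx - half_bins, 0)
    hi = np.minimum(idx + half_bins, n - 1)
    means = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return SmoothedProfile(
        chrom=track.chrom,
        bin_size=track.bin_size,
        values=np.log2(pseudocount + means),
        pseudocount=pseudocount,
        window=window,
    )


def replicate_correlation(a: SmoothedProfile, b: SmoothedProfile) -> float:
    """Pearson correlation between two profiles' per-bin values.

    Returns NaN when either profile has zero variance (undefined).
    """
    if a.values.shape != b.values.shape:
        raise ValueError("profiles must have matching shape")
    if np.std(a.values) == 0 or np.std(b.values) == 0:
        return float("nan")
    return float(np.corrcoef(a.values, b.values)[0, 1])


def genome_wide_correlation(
    a: dict[str, SmoothedProfile], b: dict[str, SmoothedProfile]
) -> float:
    """Pearson correlation over all bins of all shared chromosomes."""
    chroms = sorted(set(a) & set(b))
    if not chroms:
        raise ValueError("no shared chromosomes")
    va = np.concatenate([a[c].values for c in chroms])
    vb = np.concatenate([b[c].values for c in chroms])
    if np.std(va) == 0 or np.std(vb) == 0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def call_contact_regions(
    profile: SmoothedProfile, threshold: float = DEFAULT_THRESHOLD
) -> list[ContactRegion]:
    """Maximal runs of consecutive bins with smoothed log2 signal strictly
    above ``threshold``, emitted as intervals with their peak value."""
    above = profile.values > threshold
    regions: list[ContactRegion] = []
    n = len(above)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        regions.append(
            ContactRegion(
                interval=GenomicInterval(
                    profile.chrom,
                    i * profile.bin_size,
                    (j + 1) * profile.bin_size,
                ),
                peak_value=float(profile.values[i : j + 1].max()),
                threshold=threshold,
            )
        )
        i = j + 1
    return regions
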