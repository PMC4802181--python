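"""Shared format readers and writers.

BED and bedGraph are 0-based half-open, GTF-lite is 1-based inclusive;
all records are 0-based half-open in memory and converted only here.
Malformed lines raise with their line number.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .fourc import BinnedTrack, ContactRegion, SmoothedProfile
from .genome import GeneRecord, GenomicInterval, ReadRecord
from .splicing import JUNCTION_COLUMNS, Junction


class FormatError(ValueError):
    pass


# --------------------------------------------------------------------- BED


def write_bed_reads(reads: list[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")


def read_bed_reads(path: str | Path) -> list[ReadRecord]:
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: need >= 3 BED fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "+"
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end for {name}")
            reads.append(ReadRecord(chrom, start, end, strand, name))
    return reads


def write_bed_regions(regions: list[ContactRegion], path: str | Path) -> None:
    """Contact regions as BED3 + score (peak log2 value)."""
    with open(path, "w") as fh:
        for r in regions:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.peak_value:.4f}\n")


def write_bed_genes(genes: list[GeneRecord], path: str | Path) -> None:
    """Genes as BED6 + a 7th gene-class column + an 8th expression column."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}"
                f"\t{g.gene_class}\t{g.expression:.6g}\n"
            )


def read_bed_genes(path: str | Path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise FormatError(
                    f"{path}:{lineno}: gene BED needs >= 7 fields (class column)"
                )
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), fields[5]
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            expression = float(fields[7]) if len(fields) > 7 else 0.0
            genes.append(GeneRecord(fields[3], iv, fields[6], expression))
    return genes


# ---------------------------------------------------------------- bedGraph


def write_bedgraph(
    track: BinnedTrack | SmoothedProfile, path: str | Path
) -> None:
    values = track.counts if isinstance(track, BinnedTrack) else track.values
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            start = i * track.bin_size
            fh.write(f"{track.chrom}\t{start}\t{start + track.bin_size}\t{v}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "value"], comment="#"
    )
    if df.isna().any().any():
        raise FormatError(f"{path}: malformed bedGraph")
    return df


# ---------------------------------------------------------------- GTF-lite


def write_gtf_lite(genes: list[GeneRecord], path: str | Path) -> None:
    """Gene-level GTF records (1-based inclusive) with gene_id/gene_class."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_class "{g.gene_class}";'
            fh.write(
                f"{iv.chrom}\tnbconform\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


def read_gtf_lite(path: str | Path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: GTF needs 9 fields")
            if fields[2] != "gene":
                continue
            attrs = {}
            for part in fields[8].split(";"):
                part = part.strip()
                if not part:
                    continue
                key, _, val = part.partition(" ")
                attrs[key] = val.strip('"')
            if "gene_id" not in attrs:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            genes.append(
                GeneRecord(attrs["gene_id"], iv, attrs.get("gene_class", "other"))
            )
    return genes


# ------------------------------------------------------------------- FASTQ


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    """FASTQ records as (id, sequence, phred qualities)."""
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            records.append(
                (rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"]))
            )
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FASTQ record {len(records) + 1}: {exc}") from exc
    return records


def write_fastq(records: list[tuple[str, str, list[int]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, quals in records:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{read_id}\n{seq}\n+\n{qstr}\n")


# ----------------------------------------------------------- TSV / CSV tables


def write_junctions_tsv(junctions: list[Junction], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": j.chrom,
                "donor": j.donor,
                "acceptor": j.acceptor,
                "strand": j.strand,
                "count": j.count,
                "gene_id": j.gene_id,
            }
            for j in junctions
        ],
        columns=JUNCTION_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_junctions_tsv(path: str | Path) -> list[Junction]:
    df = pd.read_csv(path, sep="\t")
    missing = set(JUNCTION_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing junction columns {sorted(missing)}")
    junctions = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        try:
            junctions.append(
                Junction(
                    str(row.chrom),
                    int(row.donor),
                    int(row.acceptor),
                    str(row.strand),
                    int(row.count),
                    str(getattr(row, "gene_id", ".")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    return junctions


def write_spot_table_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_spot_table_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "channel", "x_px", "y_px"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing spot-table columns {sorted(missing)}")
    if "intensity" not in df.columns:
        df["intensity"] = 0.0
    return df
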