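"""Readers and writers for the standard text formats.

BED / bedGraph / BEDPE are parsed as 0-based half-open.  Gene and
differential-expression tables are tab-separated with a header row.
Parsers raise :class:`ParseError` naming the offending line.
"""

from __future__ import annotations

import os
from typing import Optional, Union

import pandas as pd

from .core import ChromatinContact, GeneRecord, GenomicInterval
from .tracks import SignalTrack

__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_bedpe",
    "write_bedpe",
    "read_gene_table",
    "write_gene_table",
    "read_de_table",
]

PathLike = Union[str, os.PathLike]

GENE_TABLE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss", "biotype"]
DE_TABLE_COLUMNS = ["feature_id", "log2fc", "q_value"]


class ParseError(ValueError):
    """Malformed row in an input file; the message names file and line."""


def _fields(line: str, path: PathLike, lineno: int, minimum: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < minimum:
        raise ParseError(
            f"{path}:{lineno}: expected >= {minimum} tab-separated fields, "
            f"got {len(fields)}"
        )
    return fields


def _coords(fields: list[str], offset: int, path: PathLike, lineno: int) -> tuple[int, int]:
    try:
        start, end = int(fields[offset]), int(fields[offset + 1])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    if not 0 <= start < end:
        raise ParseError(f"{path}:{lineno}: require 0 <= start < end, got {start}, {end}")
    return start, end


def _is_header(line: str) -> bool:
    return line.startswith(("track", "browser", "#"))


def read_bed(path: PathLike, expected_columns: Optional[int] = None) -> list[GenomicInterval]:
    """Read a BED3/BED6(+) file as a list of intervals, order preserved.

    Strand is taken from column 6 when present; the name from column 4.
    ``expected_columns`` enforces an exact column count when given.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or _is_header(line):
                continue
            fields = _fields(line, path, lineno, 3)
            if expected_columns is not None and len(fields) != expected_columns:
                raise ParseError(
                    f"{path}:{lineno}: expected exactly {expected_columns} "
                    f"columns, got {len(fields)}"
                )
            start, end = _coords(fields, 1, path, lineno)
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(fields[0], start, end, strand, name))
    return intervals


def write_bed(intervals: list[GenomicInterval], path: PathLike, columns: int = 3) -> None:
    """Write canonical BED3 or BED6 (``columns`` = 3 or 6)."""
    if columns not in (3, 6):
        raise ValueError("columns must be 3 or 6")
    with open(path, "w") as handle:
        for iv in intervals:
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if columns == 6:
                row += [iv.name or ".", "0", iv.strand]
            handle.write("\t".join(row) + "\n")


def read_bedgraph(path: PathLike) -> SignalTrack:
    """Read a bedGraph coverage file into a :class:`SignalTrack`."""
    entries = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or _is_header(line):
                continue
            fields = _fields(line, path, lineno, 4)
            start, end = _coords(fields, 1, path, lineno)
            try:
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
            entries.append((fields[0], start, end, value))
    return SignalTrack(entries)


def write_bedgraph(track: SignalTrack, path: PathLike) -> None:
    with open(path, "w") as handle:
        for chrom, start, end, value in track.to_entries():
            handle.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


def read_bedpe(path: PathLike) -> list[ChromatinContact]:
    """Read BEDPE (>= 6 columns); column 7, when present, is a source tag."""
    contacts = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or _is_header(line):
                continue
            fields = _fields(line, path, lineno, 6)
            s1, e1 = _coords(fields, 1, path, lineno)
            s2, e2 = _coords(fields, 4, path, lineno)
            source = fields[6] if len(fields) > 6 else ""
            contacts.append(
                ChromatinContact(
                    GenomicInterval(fields[0], s1, e1),
                    GenomicInterval(fields[3], s2, e2),
                    source,
                )
            )
    return contacts


def write_bedpe(contacts: list[ChromatinContact], path: PathLike) -> None:
    with open(path, "w") as handle:
        for c in contacts:
            handle.write(
                "\t".join(
                    [
                        c.anchor1.chrom, str(c.anchor1.start), str(c.anchor1.end),
                        c.anchor2.chrom, str(c.anchor2.start), str(c.anchor2.end),
                        c.source or ".",
                    ]
                )
                + "\n"
            )


def read_gene_table(path: PathLike) -> list[GeneRecord]:
    """Read the TSV gene annotation (gene_id, chrom, start, end, strand, tss, biotype)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: gene table missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        body = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                chrom=row.chrom,
                tss=int(row.tss),
                strand=row.strand,
                biotype=row.biotype,
                body=body,
            )
        )
    return genes


def write_gene_table(genes: list[GeneRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.body.start, g.body.end, g.strand, g.tss, g.biotype)
            for g in genes
        ],
        columns=GENE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_de_table(path: PathLike) -> pd.DataFrame:
    """Read a differential-expression TSV (feature_id, log2fc, q_value)."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    missing = set(DE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: DE table missing columns {sorted(missing)}")
    return df
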