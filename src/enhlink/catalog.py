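"""Merged active-enhancer catalog and TF-binding classification.

Active enhancers detected by two complementary assays — CAGE (stable eRNAs)
and GRO-seq (nascent, unstable eRNAs) — are pooled into one catalog, with
records sharing >= 1 bp merged into a single enhancer.  The catalog is then
partitioned into TF-bound and unbound classes by intersection with a ChIP-seq
peak set (for example p53 binding sites): an enhancer is bound iff any peak
overlaps its body by at least one base.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

from .core import GenomicInterval, merge_overlapping, overlaps
from .io import ParseError

__all__ = [
    "Enhancer",
    "CatalogSummary",
    "build_catalog",
    "classify_by_binding",
    "read_enhancer_bed",
    "write_catalog",
    "read_catalog",
]

PathLike = Union[str, os.PathLike]

CATALOG_COLUMNS = ["chrom", "start", "end", "name", "source", "expression", "p53_bound"]


@dataclass
class Enhancer:
    """One enhancer: an interval with an eRNA expression level.

    ``source`` is ``"CAGE"``, ``"GROseq"`` or ``"merged"``; ``p53_bound`` is
    ``None`` until :func:`classify_by_binding` runs.  ``provenance`` keeps the
    names of constituent records after merging, for audit.
    """

    interval: GenomicInterval
    source: str
    expression: float
    p53_bound: Optional[bool] = None
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.expression < 0:
            raise ValueError(
                f"enhancer {self.interval.name}: expression must be >= 0"
            )

    @property
    def name(self) -> Optional[str]:
        return self.interval.name


@dataclass(frozen=True)
class CatalogSummary:
    n_cage: int
    n_groseq: int
    n_merged: int
    n_bound: int = 0
    n_unbound: int = 0

    def __post_init__(self) -> None:
        if self.n_bound + self.n_unbound not in (0, self.n_merged):
            raise ValueError("n_bound + n_unbound must equal n_merged")


def build_catalog(
    cage: Sequence[Enhancer], groseq: Sequence[Enhancer]
) -> tuple[list[Enhancer], CatalogSummary]:
    """Pool and merge the two source sets into one enhancer catalog.

    Records overlapping by >= 1 bp collapse into one enhancer spanning their
    union; the merged expression is the max of the constituents (keeping the
    strongest evidence of activity, independent of merge order) and the
    source tag becomes ``"merged"``.  Output is sorted by position and named
    ``enh_0001`` ... in that order.
    """
    if not cage and not groseq:
        raise ValueError("cannot build a catalog from two empty enhancer sets")
    tagged = [(e, "CAGE") for e in cage] + [(e, "GROseq") for e in groseq]
    regions = merge_overlapping([e.interval for e, _ in tagged])
    # assign constituents to merged regions by overlap (each constituent hits
    # exactly one merged region, since regions cover the union disjointly)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    buckets: dict[GenomicInterval, list[tuple[Enhancer, str]]] = {r: [] for r in regions}
    for enh, tag in tagged:
        hit = next(r for r in by_chrom[enh.interval.chrom] if overlaps(r, enh.interval))
        buckets[hit].append((enh, tag))

    merged: list[Enhancer] = []
    width = max(4, len(str(len(regions))))
    for i, region in enumerate(regions, start=1):
        members = buckets[region]
        tags = {tag for _, tag in members}
        source = tags.pop() if len(members) == 1 else "merged"
        expression = max(e.expression for e, _ in members)
        provenance = tuple(
            e.interval.name or f"{tag}:{e.interval.chrom}:{e.interval.start}-{e.interval.end}"
            for e, tag in members
        )
        named = GenomicInterval(region.chrom, region.start, region.end, name=f"enh_{i:0{width}d}")
        merged.append(Enhancer(named, source, expression, provenance=provenance))
    summary = CatalogSummary(n_cage=len(cage), n_groseq=len(groseq), n_merged=len(merged))
    return merged, summary


def classify_by_binding(
    enhancers: Sequence[Enhancer], peaks: Sequence[GenomicInterval]
) -> tuple[list[Enhancer], list[Enhancer]]:
    """Partition the catalog by peak intersection (>= 1 bp anywhere in the body).

    Sets ``p53_bound`` on every enhancer and returns ``(bound, unbound)``;
    an empty peak set is legal and leaves every enhancer unbound.
    """
    peaks_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    bound, unbound = [], []
    for enh in enhancers:
        hit = any(
            overlaps(enh.interval, p)
            for p in peaks_by_chrom.get(enh.interval.chrom, ())
        )
        enh.p53_bound = hit
        (bound if hit else unbound).append(enh)
    return bound, unbound


def read_enhancer_bed(path: PathLike, source: str) -> list[Enhancer]:
    """Read a BED6+1 enhancer file; column 7 is the eRNA expression level."""
    enhancers = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}:{lineno}: expected BED6+1 with expression in column 7")
            try:
                start, end, expression = int(fields[1]), int(fields[2]), float(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed coordinates or expression") from exc
            if not 0 <= start < end:
                raise ParseError(f"{path}:{lineno}: require 0 <= start < end")
            name = fields[3] if fields[3] != "." else None
            interval = GenomicInterval(fields[0], start, end, fields[5], name)
            enhancers.append(Enhancer(interval, source, expression))
    return enhancers


def write_catalog(enhancers: Sequence[Enhancer], path: PathLike) -> None:
    rows = [
        (
            e.interval.chrom, e.interval.start, e.interval.end,
            e.interval.name or ".", e.source, e.expression,
            "" if e.p53_bound is None else int(e.p53_bound),
        )
        for e in enhancers
    ]
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalog(path: PathLike) -> list[Enhancer]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: catalog missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        interval = GenomicInterval(
            row.chrom, int(row.start), int(row.end),
            name=None if row.name in (".", None) else str(row.name),
        )
        bound = None if pd.isna(row.p53_bound) or row.p53_bound == "" else bool(int(row.p53_bound))
        out.append(Enhancer(interval, row.source, float(row.expression), bound))
    return out
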