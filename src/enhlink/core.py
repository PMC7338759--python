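"""Coordinate conventions and interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Published enhancer tables usually print 1-based inclusive coordinates; those
are converted (``start - 1``) when fixtures are loaded, never here.

Chromosome names are compared by exact string equality; no ``chr`` aliasing
is performed.  :func:`check_chrom_consistency` reports mismatched name sets
between inputs instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "ChromatinContact",
    "GeneRecord",
    "overlaps",
    "interval_distance",
    "center",
    "merge_overlapping",
    "check_chrom_consistency",
]

#: strand value for unstranded features
UNSTRANDED = "."


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates.

    Parameters
    ----------
    chrom : str
        Chromosome name (matched by exact string equality).
    start, end : int
        0-based half-open bounds; ``0 <= start < end`` is enforced.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    name : str, optional
        Free-text identifier.
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_point(self, chrom: str, pos: int) -> bool:
        """True iff ``pos`` (0-based) lies within this interval."""
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class ChromatinContact:
    """A pairwise chromatin-interaction record (one BEDPE row).

    The two anchors may lie on different chromosomes.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    source: str = ""


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its TSS annotation.

    ``biotype`` is ``"miRNA"`` or anything else (treated as non-miRNA).
    The TSS must lie within the gene body.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    biotype: str
    body: GenomicInterval = field(repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.body.contains_point(self.chrom, self.tss):
            raise ValueError(
                f"gene {self.gene_id}: TSS {self.tss} outside body "
                f"{self.body.chrom}:{self.body.start}-{self.body.end}"
            )

    @property
    def is_mirna(self) -> bool:
        return self.biotype == "miRNA"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base.

    Half-open semantics: adjacent intervals (``a.end == b.start``) do not
    overlap.
    """
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Gap in bp between two intervals; 0 if they overlap.

    Returns ``None`` for intervals on different chromosomes (the distance is
    undefined there, and callers must treat it as such rather than as a large
    number).
    """
    if a.chrom != b.chrom:
        return None
    gap = max(a.start, b.start) - min(a.end, b.end)
    return max(gap, 0)


def center(a: GenomicInterval) -> int:
    """Midpoint of the interval, rounded down for odd lengths."""
    return (a.start + a.end) // 2


def merge_overlapping(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals that share >= 1 bp.

    Returns a sorted, pairwise-disjoint list covering exactly the union of
    the input bases.  Adjacent-but-not-overlapping intervals are kept
    separate.  Strand and name are dropped on merged output (a merged region
    has no single identity).
    """
    items = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in items:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def check_chrom_consistency(
    named_sets: dict[str, Sequence[str]], stacklevel: int = 2
) -> list[str]:
    """Warn when inputs use different chromosome name sets.

    ``named_sets`` maps an input label to the chromosome names it mentions.
    Returns the warning messages (also emitted via :mod:`warnings`).
    """
    sets = {label: set(names) for label, names in named_sets.items()}
    union = set().union(*sets.values()) if sets else set()
    messages = []
    for label, names in sets.items():
        missing = union - names
        if missing and names:
            msg = (
                f"input {label!r} lacks chromosomes {sorted(missing)} "
                "present in other inputs (names are matched exactly)"
            )
            messages.append(msg)
            warnings.warn(msg, stacklevel=stacklevel)
    return messages
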