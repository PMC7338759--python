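"""Enhancer-target assignment by TAD, chromatin-contact, and distance evidence.

Differentially expressed miRNAs and mRNAs are assigned to TF-bound enhancers
by the union of three independent lines of evidence:

1. **TAD co-membership** — the enhancer center and the target's TSS fall in
   the same topologically associating domain.
2. **Chromatin contact** — a curated interaction record has one anchor
   overlapping the enhancer and the other overlapping the target promoter
   (either orientation, >= 1 bp).
3. **Distance** — for mRNAs, the promoter lies within 100 kb of the
   enhancer (inclusive).  For miRNAs, the linkage score

       S = (B - A) / (A + B)

   where A is the distance from the enhancer center to the closest miRNA
   gene TSS and B the distance to the closest non-miRNA gene TSS; the
   closest miRNA is enhancer-associated when S is strictly below 0.2
   (equivalently B < 1.5 A).

Promoters are strand-aware windows from 1 kb upstream to 500 bp downstream
of the TSS.  A link is emitted for a (bound enhancer, DE target) pair iff at
least one evidence type holds; only significantly DE targets are eligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .catalog import Enhancer
from .core import (
    ChromatinContact,
    GeneRecord,
    GenomicInterval,
    center,
    interval_distance,
    overlaps,
)

__all__ = [
    "Promoter",
    "LinkageScore",
    "TargetLink",
    "LinkConfig",
    "derive_promoter",
    "validate_tads",
    "tad_evidence",
    "contact_evidence",
    "linkage_score",
    "distance_evidence_mirna",
    "distance_evidence_mrna",
    "integrate_links",
    "dual_target_enhancers",
]

EVIDENCE_TYPES = ("distance", "tad", "contact")


@dataclass(frozen=True)
class Promoter:
    """Strand-aware promoter window around a TSS (1500 bp by default)."""

    gene_id: str
    interval: GenomicInterval
    tss: int
    strand: str


@dataclass(frozen=True)
class LinkageScore:
    """The (A, B, S) triple for one enhancer-miRNA distance evaluation."""

    enhancer_id: str
    mirna_id: str
    A: float
    B: float
    S: float


@dataclass(frozen=True)
class TargetLink:
    """One enhancer-target assignment with its supporting evidence flags."""

    enhancer_id: str
    target_id: str
    target_type: str  # "miRNA" or "mRNA"
    evidence: frozenset[str]
    log2fc: float

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("a TargetLink requires at least one evidence type")
        unknown = set(self.evidence) - set(EVIDENCE_TYPES)
        if unknown:
            raise ValueError(f"unknown evidence types {sorted(unknown)}")


@dataclass(frozen=True)
class LinkConfig:
    """Tunables of the assignment procedure with their default readings.

    ``s_threshold`` is compared strictly (score *below* 0.2 associates);
    ``mrna_window`` is inclusive.  ``require_mirna_closer`` optionally adds
    the condition A <= B to the miRNA distance rule, restricting it to cases
    where the miRNA really is the nearest gene; off by default, which applies
    the score formula exactly as stated.  ``tad_mode`` tests co-membership by
    representative points ("point": enhancer center and promoter TSS) or by
    full interval overlap with one TAD ("overlap").
    """

    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    s_threshold: float = 0.2
    mrna_window: int = 100_000
    require_mirna_closer: bool = False
    tad_mode: str = "point"

    def __post_init__(self) -> None:
        if self.promoter_upstream <= 0 or self.promoter_downstream <= 0:
            raise ValueError("promoter extents must be positive")
        if self.mrna_window <= 0:
            raise ValueError("mrna_window must be positive")
        if self.tad_mode not in ("point", "overlap"):
            raise ValueError("tad_mode must be 'point' or 'overlap'")


def derive_promoter(
    gene: GeneRecord, upstream: int = 1000, downstream: int = 500
) -> Promoter:
    """Promoter = [TSS - upstream, TSS + downstream) on the coding strand.

    On the minus strand the window is reflected: [TSS - downstream,
    TSS + upstream).  Windows running off the chromosome start are clipped
    at 0 with a warning (the promoter is then shorter than nominal).
    """
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    elif gene.strand == "-":
        start, end = gene.tss - downstream, gene.tss + upstream
    else:
        raise ValueError(f"gene {gene.gene_id}: unknown strand {gene.strand!r}")
    if start < 0:
        warnings.warn(
            f"promoter of {gene.gene_id} clipped at chromosome start", stacklevel=2
        )
        start = 0
    return Promoter(
        gene_id=gene.gene_id,
        interval=GenomicInterval(gene.chrom, start, end, gene.strand, gene.gene_id),
        tss=gene.tss,
        strand=gene.strand,
    )


def validate_tads(tads: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Check TADs are pairwise non-overlapping per chromosome; return sorted."""
    ordered = sorted(tads, key=lambda t: (t.chrom, t.start))
    for prev, cur in zip(ordered, ordered[1:]):
        if prev.chrom == cur.chrom and cur.start < prev.end:
            raise ValueError(
                f"overlapping TADs on {cur.chrom}: "
                f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
            )
    return ordered


def tad_evidence(
    enhancer: Enhancer,
    promoter: Promoter,
    tads: Sequence[GenomicInterval],
    mode: str = "point",
) -> bool:
    """True iff one TAD holds both the enhancer and the promoter.

    In "point" mode (default) the representative points are the enhancer
    center and the promoter TSS, which is well defined even for intervals
    straddling a TAD boundary; "overlap" mode instead requires one TAD to
    overlap both whole intervals by >= 1 bp.
    """
    e_iv = enhancer.interval
    if e_iv.chrom != promoter.interval.chrom:
        return False
    if mode == "point":
        c = center(e_iv)
        return any(
            t.contains_point(e_iv.chrom, c)
            and t.contains_point(promoter.interval.chrom, promoter.tss)
            for t in tads
        )
    if mode == "overlap":
        return any(
            overlaps(t, e_iv) and overlaps(t, promoter.interval) for t in tads
        )
    raise ValueError(f"unknown tad mode {mode!r}")


def contact_evidence(
    enhancer: Enhancer,
    promoter: Promoter,
    contacts: Sequence[ChromatinContact],
) -> bool:
    """True iff a contact joins the enhancer and the promoter (>= 1 bp per anchor).

    Both anchor orientations are tested.
    """
    e_iv, p_iv = enhancer.interval, promoter.interval
    return any(
        (overlaps(c.anchor1, e_iv) and overlaps(c.anchor2, p_iv))
        or (overlaps(c.anchor2, e_iv) and overlaps(c.anchor1, p_iv))
        for c in contacts
    )


def linkage_score(A: float, B: float) -> float:
    """Distance-based linkage score S = (B - A) / (A + B).

    A and B are nonnegative distances (bp) from the enhancer center to the
    closest miRNA gene and the closest non-miRNA gene; S always lies in
    [-1, 1].  Both distances zero leaves S undefined and raises.
    """
    if A < 0 or B < 0:
        raise ValueError("distances must be nonnegative")
    if A + B == 0:
        raise ValueError(
            "linkage score undefined: enhancer center coincides with both "
            "nearest gene TSSs (A + B = 0)"
        )
    return (B - A) / (A + B)


def distance_evidence_mirna(
    enhancer: Enhancer,
    genes: Sequence[GeneRecord],
    s_threshold: float = 0.2,
    require_mirna_closer: bool = False,
) -> list[tuple[str, LinkageScore]]:
    """Distance rule for miRNAs: score the closest miRNA gene against S < 0.2.

    A = distance from the enhancer center to the closest miRNA TSS on the
    same chromosome; B = distance to the closest non-miRNA TSS.  When S is
    strictly below ``s_threshold``, every miRNA tied at distance A is
    returned (ordered by gene_id); otherwise the list is empty.  Missing
    miRNA or non-miRNA genes on the chromosome yield an empty result with a
    warning.
    """
    chrom = enhancer.interval.chrom
    c = center(enhancer.interval)
    mirna_d: dict[str, int] = {}
    other_best: Optional[int] = None
    for g in genes:
        if g.chrom != chrom:
            continue
        d = abs(g.tss - c)
        if g.is_mirna:
            mirna_d[g.gene_id] = d
        elif other_best is None or d < other_best:
            other_best = d
    if not mirna_d or other_best is None:
        warnings.warn(
            f"enhancer {enhancer.name}: chromosome {chrom} lacks "
            f"{'miRNA' if not mirna_d else 'non-miRNA'} genes; "
            "distance evidence skipped",
            stacklevel=2,
        )
        return []
    A = min(mirna_d.values())
    B = other_best
    S = linkage_score(A, B)
    if S >= s_threshold:
        return []
    if require_mirna_closer and A > B:
        return []
    eid = enhancer.name or f"{chrom}:{enhancer.interval.start}-{enhancer.interval.end}"
    return [
        (gid, LinkageScore(eid, gid, float(A), float(B), S))
        for gid in sorted(g for g, d in mirna_d.items() if d == A)
    ]


def distance_evidence_mrna(
    enhancer: Enhancer, promoter: Promoter, window: int = 100_000
) -> bool:
    """True iff the promoter lies within ``window`` bp of the enhancer (inclusive)."""
    d = interval_distance(enhancer.interval, promoter.interval)
    return d is not None and d <= window


def integrate_links(
    bound_enhancers: Sequence[Enhancer],
    genes: Sequence[GeneRecord],
    de_log2fc: dict[str, float],
    tads: Sequence[GenomicInterval],
    contacts: Sequence[ChromatinContact],
    config: LinkConfig = LinkConfig(),
) -> list[TargetLink]:
    """Union of the three evidence types over all (bound enhancer, DE target) pairs.

    ``genes`` is the full annotation (nearest-gene distances for the miRNA
    score are measured against every annotated gene); ``de_log2fc`` maps the
    significantly DE feature ids to their log2 fold change and defines the
    target universe.  Each method is evaluated independently for every pair
    and a link is emitted iff at least one holds.
    """
    tads = validate_tads(tads)
    de_genes = [g for g in genes if g.gene_id in de_log2fc]
    promoters = {
        g.gene_id: derive_promoter(g, config.promoter_upstream, config.promoter_downstream)
        for g in de_genes
    }
    links: list[TargetLink] = []
    for enh in bound_enhancers:
        evidence: dict[str, set[str]] = {}
        for gid, score in distance_evidence_mirna(
            enh, genes, config.s_threshold, config.require_mirna_closer
        ):
            if gid in de_log2fc:
                evidence.setdefault(gid, set()).add("distance")
        for g in de_genes:
            prom = promoters[g.gene_id]
            if tad_evidence(enh, prom, tads, config.tad_mode):
                evidence.setdefault(g.gene_id, set()).add("tad")
            if contact_evidence(enh, prom, contacts):
                evidence.setdefault(g.gene_id, set()).add("contact")
            if not g.is_mirna and distance_evidence_mrna(enh, prom, config.mrna_window):
                evidence.setdefault(g.gene_id, set()).add("distance")
        eid = enh.name or f"{enh.interval.chrom}:{enh.interval.start}-{enh.interval.end}"
        biotype = {g.gene_id: ("miRNA" if g.is_mirna else "mRNA") for g in genes}
        for gid in sorted(evidence):
            links.append(
                TargetLink(
                    enhancer_id=eid,
                    target_id=gid,
                    target_type=biotype[gid],
                    evidence=frozenset(evidence[gid]),
                    log2fc=de_log2fc[gid],
                )
            )
    return links


def dual_target_enhancers(links: Sequence[TargetLink]) -> list[tuple[str, int, int]]:
    """Enhancers linked to both a miRNA and an mRNA target.

    Returns ``(enhancer_id, n_mirna, n_mrna)`` tuples, ordered by id.
    """
    counts: dict[str, dict[str, int]] = {}
    for link in links:
        counts.setdefault(link.enhancer_id, {"miRNA": 0, "mRNA": 0})
        counts[link.enhancer_id][link.target_type] += 1
    return [
        (eid, c["miRNA"], c["mRNA"])
        for eid, c in sorted(counts.items())
        if c["miRNA"] >= 1 and c["mRNA"] >= 1
    ]
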