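"""End-to-end orchestration: catalog -> classify -> profile -> DE filter -> link.

A :class:`PipelineConfig` names every input file and centralizes every
numeric threshold of the procedure.  :func:`run_all` executes the stages,
writes the intermediate tables and a machine-readable report under one
output directory, and returns the :class:`RunReport`.  Reruns on unchanged
inputs are byte-identical (no timestamps in any output).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from . import __version__
from .catalog import (
    CatalogSummary,
    Enhancer,
    build_catalog,
    classify_by_binding,
    read_enhancer_bed,
    write_catalog,
)
from .core import check_chrom_consistency
from .defilter import apply_de_thresholds, significant_log2fc
from .io import read_bed, read_bedgraph, read_bedpe, read_de_table, read_gene_table
from .linkage import LinkConfig, TargetLink, dual_target_enhancers, integrate_links
from .profiles import extract_profile, mean_signal_ratio, rank_tracks

__all__ = ["PipelineConfig", "RunReport", "run_all", "write_links"]

PathLike = Union[str, os.PathLike]

logger = logging.getLogger("enhlink")

LINK_COLUMNS = [
    "enhancer_chrom", "enhancer_start", "enhancer_end",
    "target_id", "target_type", "log2fc",
    "evidence_distance", "evidence_tad", "evidence_contact",
]


@dataclass
class PipelineConfig:
    """Input paths plus every tunable threshold, in one place.

    Relative input paths are resolved against ``base_dir``.
    """

    cage: str = "cage_enhancers.bed"
    groseq: str = "groseq_enhancers.bed"
    peaks: str = "p53_peaks.bed"
    tads: str = "tads.bed"
    contacts: str = "contacts.bedpe"
    genes: str = "genes.tsv"
    de_mirna: str = "de_mirna.tsv"
    de_mrna: str = "de_mrna.tsv"
    tracks_manifest: str = "tracks_manifest.tsv"
    base_dir: str = "."

    flank: int = 1000
    bin_width: int = 10
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    s_threshold: float = 0.2
    mrna_window: int = 100_000
    de_q: float = 0.05
    de_lfc: float = 1.0
    require_mirna_closer: bool = False
    tad_mode: str = "point"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flank", "bin_width", "promoter_upstream",
                     "promoter_downstream", "mrna_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("s_threshold", "de_q", "de_lfc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def path(self, name: str) -> Path:
        return Path(self.base_dir) / getattr(self, name)

    def link_config(self) -> LinkConfig:
        return LinkConfig(
            promoter_upstream=self.promoter_upstream,
            promoter_downstream=self.promoter_downstream,
            s_threshold=self.s_threshold,
            mrna_window=self.mrna_window,
            require_mirna_closer=self.require_mirna_closer,
            tad_mode=self.tad_mode,
        )

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @classmethod
    def from_bundle(cls, bundle_dir: PathLike, **overrides) -> "PipelineConfig":
        """Config pointing at a directory laid out by the synthetic generator."""
        return cls(base_dir=str(bundle_dir), **overrides)


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    catalog: CatalogSummary
    tracks: list[dict]
    n_tracks_higher: int
    n_tracks_lower: int
    de_counts: dict[str, dict[str, int]]
    n_links: int
    links_by_type: dict[str, int]
    links_by_evidence: dict[str, int]
    dual_target_enhancers: list[dict]
    config: dict
    version: str = field(default=__version__)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["catalog"] = dataclasses.asdict(self.catalog)
        return d


def _evidence_key(link: TargetLink) -> str:
    return "+".join(e for e in ("distance", "tad", "contact") if e in link.evidence)


def write_links(
    links: list[TargetLink], enhancer_by_id: dict[str, Enhancer], path: PathLike
) -> None:
    """Serialize links in the published table's schema (0-based starts)."""
    rows = []
    for link in links:
        iv = enhancer_by_id[link.enhancer_id].interval
        rows.append(
            (
                iv.chrom, iv.start, iv.end,
                link.target_id, link.target_type, link.log2fc,
                int("distance" in link.evidence),
                int("tad" in link.evidence),
                int("contact" in link.evidence),
            )
        )
    pd.DataFrame(rows, columns=LINK_COLUMNS).to_csv(path, sep="\t", index=False)


def run_all(config: PipelineConfig, out_dir: PathLike) -> RunReport:
    """Run every stage and write catalog/comparisons/profiles/links/report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage=catalog reading %s and %s", config.path("cage"), config.path("groseq"))
    cage = read_enhancer_bed(config.path("cage"), "CAGE")
    groseq = read_enhancer_bed(config.path("groseq"), "GROseq")
    enhancers, summary = build_catalog(cage, groseq)

    logger.info("stage=classify reading %s", config.path("peaks"))
    peaks = read_bed(config.path("peaks"))
    bound, unbound = classify_by_binding(enhancers, peaks)
    summary = CatalogSummary(
        n_cage=summary.n_cage, n_groseq=summary.n_groseq,
        n_merged=summary.n_merged, n_bound=len(bound), n_unbound=len(unbound),
    )
    write_catalog(enhancers, out / "catalog.tsv")
    logger.info("stage=classify n_merged=%d n_bound=%d", summary.n_merged, summary.n_bound)

    check_chrom_consistency(
        {
            "enhancers": [e.interval.chrom for e in enhancers],
            "peaks": [p.chrom for p in peaks],
        }
    )

    # --- per-track class comparison and metaprofiles
    manifest = pd.read_csv(config.path("tracks_manifest"), sep="\t")
    comparisons = []
    profile_rows = []
    for row in manifest.itertuples(index=False):
        track_path = Path(config.base_dir) / row.path
        logger.info("stage=profile track=%s", row.track_name)
        track = read_bedgraph(track_path)
        comparisons.append(
            mean_signal_ratio(track, bound, unbound, config.flank, row.track_name)
        )
        for cls_name, cls in (("bound", bound), ("unbound", unbound)):
            prof = extract_profile(track, cls, config.flank, config.bin_width)
            meta = prof.metaprofile()
            offsets = prof.bin_centers
            profile_rows.extend(
                (row.track_name, cls_name, float(o), float(m))
                for o, m in zip(offsets, meta)
            )
    ranked = rank_tracks(comparisons)
    pd.DataFrame(
        [
            (c.track_name, c.mean_bound, c.mean_unbound, c.ratio, c.p_value, c.q_value)
            for c in ranked.comparisons
        ],
        columns=["track_name", "mean_bound", "mean_unbound", "ratio", "p_value", "q_value"],
    ).to_csv(out / "comparisons.tsv", sep="\t", index=False)
    pd.DataFrame(
        profile_rows, columns=["track", "class", "offset", "mean_signal"]
    ).to_csv(out / "profiles.tsv", sep="\t", index=False)

    # --- DE filtering
    de_counts = {}
    de_map: dict[str, float] = {}
    for label, key in (("miRNA", "de_mirna"), ("mRNA", "de_mrna")):
        table = read_de_table(config.path(key))
        labelled, n_up, n_down = apply_de_thresholds(table, config.de_q, config.de_lfc)
        labelled.to_csv(out / f"{key}_filtered.tsv", sep="\t", index=False)
        de_counts[label] = {"up": n_up, "down": n_down, "significant": n_up + n_down}
        de_map.update(significant_log2fc(table, config.de_q, config.de_lfc))
        logger.info("stage=defilter type=%s up=%d down=%d", label, n_up, n_down)

    # --- target linkage
    genes = read_gene_table(config.path("genes"))
    tads = read_bed(config.path("tads"))
    contacts = read_bedpe(config.path("contacts"))
    links = integrate_links(bound, genes, de_map, tads, contacts, config.link_config())
    enhancer_by_id = {e.interval.name: e for e in enhancers}
    write_links(links, enhancer_by_id, out / "links.tsv")
    duals = dual_target_enhancers(links)
    logger.info("stage=link n_links=%d n_dual=%d", len(links), len(duals))

    by_type: dict[str, int] = {}
    by_evidence: dict[str, int] = {}
    for link in links:
        by_type[link.target_type] = by_type.get(link.target_type, 0) + 1
        key = _evidence_key(link)
        by_evidence[key] = by_evidence.get(key, 0) + 1

    report = RunReport(
        catalog=summary,
        tracks=[
            {
                "track_name": c.track_name,
                "mean_bound": c.mean_bound,
                "mean_unbound": c.mean_unbound,
                "ratio": c.ratio,
                "p_value": c.p_value,
                "q_value": c.q_value,
            }
            for c in ranked.comparisons
        ],
        n_tracks_higher=ranked.n_higher,
        n_tracks_lower=ranked.n_lower,
        de_counts=de_counts,
        n_links=len(links),
        links_by_type=dict(sorted(by_type.items())),
        links_by_evidence=dict(sorted(by_evidence.items())),
        dual_target_enhancers=[
            {"enhancer_id": eid, "n_mirna": nm, "n_mrna": nr} for eid, nm, nr in duals
        ],
        config=dataclasses.asdict(config),
    )
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    return report
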