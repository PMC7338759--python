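"""Synthetic regulatory-genome generator with planted ground truth.

Emulates the products of the upstream assays — an enhancer catalog from two
sources with class-dependent eRNA expression, TF ChIP-seq peaks over a
subset of enhancers, coverage tracks with center-peaked signal bumps, a TAD
partition, chromatin-contact pairs, a TSS annotation, and DE tables — so the
whole inference chain can be exercised and scored against known truth
without any downloads.

Geometry is engineered so planted enhancer-target links are the *only*
(bound enhancer, DE target) pairs any evidence type can connect:

* every TF-bound enhancer sits alone near the middle of its own TAD, so
  TAD co-membership cannot fire across enhancers;
* TADs are wide enough that targets in one TAD are farther than the mRNA
  distance window from every other bound enhancer;
* contact-planted targets live in TADs hosting no bound enhancer, so when a
  contact record is withheld (``contact_recall`` < 1) no other evidence
  rescues the pair;
* each bound enhancer gets two non-DE "guard" genes — a miRNA at ~5 kb and
  a non-miRNA at ~9 kb — pinning its nearest-gene distances so the miRNA
  linkage score never fires by accident (the guard geometry keeps
  B >= 1.5 A) and never on a DE gene;
* only planted targets are significantly DE, so the DE filter removes every
  background gene from the target universe.

With ``noise_sd = 0`` the coverage bumps make the class mean-signal ratio
exactly ``amplitude_ratio``, because every enhancer has the same length and
bump shape.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import ChromatinContact, GeneRecord, GenomicInterval
from .io import write_bedpe, write_gene_table
from .linkage import TargetLink

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "load_table1",
    "make_table1_fixture",
    "table1_links",
]

PathLike = Union[str, os.PathLike]

TRACKS = (("H3K27ac", "histone"), ("H3K4me1", "histone"), ("TP53", "tf"))

TRACK_BIN = 20          # bp, bedGraph resolution around enhancer centers
TRACK_FLANK = 2000      # bp, signal written in +/- this window per enhancer
GUARD_MIRNA_BP = (4500, 5500)   # nearest-miRNA guard distance range
GUARD_OTHER_BP = (8500, 9500)   # nearest-other-gene guard distance range
MIN_ENH_SPACING = 6000  # keeps +/- TRACK_FLANK windows disjoint


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    Defaults follow the tested recovery setting: 200 enhancers of which 30%
    are TF-bound, bound-class signal bumps twice the unbound amplitude, one
    expected planted target per bound enhancer, planted DE fold changes
    around 2 (log2), and a doubled eRNA expression on the bound class.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 5_000_000
    n_genes: int = 120              # background (never-DE) genes
    mirna_fraction: float = 0.25
    n_enhancers: int = 200
    enhancer_length: int = 600
    bound_fraction: float = 0.3
    bump_amplitude_unbound: float = 10.0
    amplitude_ratio: float = 2.0
    bump_sd: float = 150.0
    noise_sd: float = 0.5
    n_tads: int = 20                # per chromosome
    contact_recall: float = 1.0
    planted_link_rate: float = 1.0  # P(bound enhancer receives one target)
    n_dual: int = 0                 # bound enhancers planted with both target types
    de_lfc_mean: float = 2.0
    expression_shift: float = 2.0
    n_decoy_peaks: int = 10
    mrna_window: int = 100_000

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "n_genes", "n_enhancers", "n_tads"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("mirna_fraction", "bound_fraction", "contact_recall",
                     "planted_link_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.amplitude_ratio <= 0:
            raise ValueError("amplitude_ratio must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.enhancer_length % 2 or self.enhancer_length <= 0:
            raise ValueError("enhancer_length must be positive and even")

    @property
    def tad_width(self) -> int:
        return self.chrom_length // self.n_tads

    @property
    def n_bound(self) -> int:
        return int(round(self.n_enhancers * self.bound_fraction))


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded alongside the generated bundle."""

    bound_ids: list[str]
    true_links: list[dict]          # enhancer_id, target_id, target_type, evidence
    planted_amplitudes: dict[str, float]
    planted_de: dict[str, float]
    amplitude_ratio: float
    expression_shift: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))

    def link_pairs(self) -> set[tuple[str, str]]:
        return {(l["enhancer_id"], l["target_id"]) for l in self.true_links}


def _check_geometry(cfg: SyntheticConfig) -> None:
    w = cfg.tad_width
    total_tads = cfg.n_chromosomes * cfg.n_tads
    if not 0 <= cfg.n_dual <= cfg.n_bound:
        raise ValueError("n_dual must lie in [0, n_bound]")
    if cfg.n_bound >= total_tads:
        raise ValueError(
            f"infeasible geometry: {cfg.n_bound} bound enhancers need more "
            f"TADs than the {total_tads} available (each bound enhancer "
            "occupies its own TAD, and contact targets need spare TADs)"
        )
    if int(0.38 * w) <= 20_000:
        raise ValueError("infeasible geometry: TADs too narrow for in-TAD targets")
    if w // 10 + GUARD_OTHER_BP[1] >= w // 2:
        raise ValueError("infeasible geometry: TADs too narrow for guard genes")
    # targets of one TAD must stay beyond the mRNA window of neighbours
    if int(0.42 * w) <= cfg.mrna_window + 2500:
        raise ValueError(
            "infeasible geometry: TAD width too small for the mRNA distance "
            "window; cross-TAD pairs could fire the distance rule"
        )


def _rand_sign(rng: np.random.Generator) -> int:
    return 1 if rng.random() < 0.5 else -1


def generate(
    config: SyntheticConfig, out_dir: PathLike
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Write the full input bundle under ``out_dir`` and return its truth.

    The same config (seed included) always produces byte-identical files.
    Returns a mapping of logical names to paths plus the
    :class:`SyntheticTruth`; the truth is also written as ``truth.json``.
    """
    _check_geometry(config)
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    w = cfg.tad_width

    # --- TAD partition: each chromosome tiled by n_tads equal domains
    tads = [
        (chrom, t * w, (t + 1) * w)
        for chrom in chroms
        for t in range(cfg.n_tads)
    ]

    # --- bound enhancers: one per randomly chosen TAD, near its middle
    n_bound = cfg.n_bound
    half = cfg.enhancer_length // 2
    tad_idx = rng.choice(len(tads), size=n_bound, replace=False)
    bound_tad = {int(i) for i in tad_idx}
    centers: list[tuple[str, int, bool]] = []  # chrom, center, bound
    for i in tad_idx:
        chrom, ts, te = tads[int(i)]
        mid = (ts + te) // 2
        c = mid + int(rng.integers(-w // 10, w // 10 + 1))
        centers.append((chrom, c, True))

    # --- unbound enhancers: anywhere, kept clear of other signal windows
    margin = TRACK_FLANK + cfg.enhancer_length
    occupied: dict[str, list[int]] = {chrom: [] for chrom in chroms}
    for chrom, c, _ in centers:
        occupied[chrom].append(c)
    n_unbound = cfg.n_enhancers - n_bound
    placed = 0
    for _ in range(200 * max(n_unbound, 1)):
        if placed == n_unbound:
            break
        chrom = chroms[int(rng.integers(len(chroms)))]
        c = int(rng.integers(margin, cfg.chrom_length - margin))
        if all(abs(c - o) >= MIN_ENH_SPACING for o in occupied[chrom]):
            occupied[chrom].append(c)
            centers.append((chrom, c, False))
            placed += 1
    if placed != n_unbound:
        raise ValueError("infeasible geometry: could not place unbound enhancers")

    # canonical order and ids: genomic sort, matching catalog naming
    centers.sort(key=lambda t: (t[0], t[1]))
    width = max(4, len(str(len(centers))))
    enhancers = []  # (eid, chrom, center, bound, interval)
    tad_of_enh: dict[str, int] = {}
    for i, (chrom, c, is_bound) in enumerate(centers, start=1):
        eid = f"enh_{i:0{width}d}"
        iv = GenomicInterval(chrom, c - half, c + half, name=eid)
        enhancers.append((eid, chrom, c, is_bound, iv))
        if is_bound:
            t_local = c // w
            tad_of_enh[eid] = chroms.index(chrom) * cfg.n_tads + t_local

    bound_ids = [eid for eid, _, _, b, _ in enhancers if b]

    # --- p53 peaks: one inside each bound enhancer, plus decoys in gaps
    peaks: list[tuple[str, int, int]] = []
    for eid, chrom, c, is_bound, _ in enhancers:
        if is_bound:
            jitter = int(rng.integers(-50, 51))
            peaks.append((chrom, c - 100 + jitter, c + 100 + jitter))
    placed = 0
    for _ in range(200 * max(cfg.n_decoy_peaks, 1)):
        if placed == cfg.n_decoy_peaks:
            break
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(margin, cfg.chrom_length - margin))
        if all(abs(s - o) >= margin + 2000 for o in occupied[chrom]):
            peaks.append((chrom, s, s + 200))
            placed += 1
    peaks.sort()

    # --- genes: guards per bound enhancer, planted targets, background
    genes: list[GeneRecord] = []
    planted_de: dict[str, float] = {}
    true_links: list[dict] = []
    contacts: list[ChromatinContact] = []

    def add_gene(gene_id: str, chrom: str, tss: int, biotype: str) -> GeneRecord:
        strand = "+" if rng.random() < 0.5 else "-"
        body = (
            GenomicInterval(chrom, tss, tss + 1000, strand)
            if strand == "+"
            else GenomicInterval(chrom, tss - 999, tss + 1, strand)
        )
        g = GeneRecord(gene_id, chrom, tss, strand, biotype, body)
        genes.append(g)
        return g

    def planted_lfc() -> float:
        sign = 1 if rng.random() < 0.8 else -1
        return sign * max(1.0, float(rng.normal(cfg.de_lfc_mean, 0.3)))

    free_tads = sorted(set(range(len(tads))) - bound_tad)
    contact_tss: dict[int, list[int]] = {}
    dual_ids = set(bound_ids[: cfg.n_dual])
    counters = {"miRNA": 0, "mRNA": 0}

    def plant_target(eid: str, chrom: str, c: int, ttype: str) -> None:
        counters[ttype] += 1
        tid = (f"tgt_mir_{counters['miRNA']:03d}" if ttype == "miRNA"
               else f"tgt_mrna_{counters['mRNA']:03d}")
        biotype = "miRNA" if ttype == "miRNA" else "protein_coding"
        evidence = ["tad", "contact", "distance"][int(rng.integers(3))]
        if evidence == "tad":
            off = _rand_sign(rng) * int(rng.integers(20_000, int(0.38 * w)))
            add_gene(tid, chrom, c + off, biotype)
        elif evidence == "distance" and ttype == "mRNA":
            hi = min(80_000, int(0.38 * w))
            off = _rand_sign(rng) * int(rng.integers(20_000, hi))
            add_gene(tid, chrom, c + off, biotype)
        elif evidence == "distance":  # miRNA: engineer S < 0.2 via B < 1.4 A
            A = int(rng.integers(2000, 2500))
            B = int(rng.integers(int(1.05 * A), int(1.4 * A)))
            add_gene(tid, chrom, c + _rand_sign(rng) * A, "miRNA")
            add_gene(f"companion_{eid}", chrom,
                     c + _rand_sign(rng) * B, "protein_coding")
        else:  # contact: target far away, in a TAD with no bound enhancer
            # keep contact targets >= 5 kb apart so no promoter overlaps
            # another pair's contact anchor
            for _ in range(200):
                ft = free_tads[int(rng.integers(len(free_tads)))]
                fchrom, fs, fe = tads[ft]
                tss = (fs + fe) // 2 + int(rng.integers(-w // 10, w // 10 + 1))
                if all(abs(tss - t) >= 5000 for t in contact_tss.get(ft, ())):
                    break
            else:
                raise ValueError("infeasible geometry: contact targets too dense")
            contact_tss.setdefault(ft, []).append(tss)
            add_gene(tid, fchrom, tss, biotype)
            contact = ChromatinContact(
                GenomicInterval(chrom, c - half, c + half),
                GenomicInterval(fchrom, tss - 1200, tss + 700),
                source="synthetic",
            )
            if rng.random() < cfg.contact_recall:
                contacts.append(contact)
        planted_de[tid] = planted_lfc()
        true_links.append(
            {"enhancer_id": eid, "target_id": tid,
             "target_type": ttype, "evidence": [evidence]}
        )

    for eid, chrom, c, is_bound, _ in enhancers:
        if not is_bound:
            continue
        # guard genes pin the nearest-gene distances (never DE)
        s1, s2 = _rand_sign(rng), _rand_sign(rng)
        add_gene(f"mir_guard_{eid}", chrom,
                 c + s1 * int(rng.integers(*GUARD_MIRNA_BP)), "miRNA")
        add_gene(f"gene_guard_{eid}", chrom,
                 c + s2 * int(rng.integers(*GUARD_OTHER_BP)), "protein_coding")
        if eid in dual_ids:
            target_types = ["miRNA", "mRNA"]
        elif rng.random() < cfg.planted_link_rate:
            target_types = ["miRNA" if rng.random() < 0.5 else "mRNA"]
        else:
            target_types = []
        for ttype in target_types:
            plant_target(eid, chrom, c, ttype)

    # background genes: never DE, kept >= 12 kb from bound enhancer centers
    bound_centers = {
        chrom: [c for eid, ch, c, b, _ in enhancers if b and ch == chrom]
        for chrom in chroms
    }
    placed = 0
    for _ in range(500 * cfg.n_genes):
        if placed == cfg.n_genes:
            break
        chrom = chroms[int(rng.integers(len(chroms)))]
        tss = int(rng.integers(2000, cfg.chrom_length - 2200))
        if all(abs(tss - c) >= 12_000 for c in bound_centers[chrom]):
            placed += 1
            biotype = "miRNA" if rng.random() < cfg.mirna_fraction else "protein_coding"
            prefix = "mir_bg" if biotype == "miRNA" else "gene_bg"
            add_gene(f"{prefix}_{placed:04d}", chrom, tss, biotype)
    if placed != cfg.n_genes:
        raise ValueError("infeasible geometry: could not place background genes")

    # --- eRNA expression: log-normal, bound class shifted multiplicatively
    expression = {
        eid: float(rng.lognormal(1.0, 0.5)) * (cfg.expression_shift if b else 1.0)
        for eid, _, _, b, _ in enhancers
    }

    # --- source membership: CAGE only / GRO-seq only / both (identical record)
    cage_rows, groseq_rows = [], []
    for eid, chrom, c, b, iv in enhancers:
        r = rng.random()
        row = (chrom, iv.start, iv.end, eid, expression[eid])
        if r < 0.60:
            cage_rows.append(row)
        elif r < 0.75:
            groseq_rows.append(row)
        else:
            cage_rows.append(row)
            groseq_rows.append(row)

    # --- coverage tracks: truncated-normal noise + Gaussian bump per center
    amp_unbound = cfg.bump_amplitude_unbound
    amp_bound = amp_unbound * cfg.amplitude_ratio
    n_bins = 2 * TRACK_FLANK // TRACK_BIN
    rel_mid = np.arange(n_bins) * TRACK_BIN - TRACK_FLANK + TRACK_BIN / 2.0
    bump_shape = np.exp(-(rel_mid**2) / (2.0 * cfg.bump_sd**2))
    track_lines: dict[str, list[str]] = {name: [] for name, _ in TRACKS}
    for name, _ in TRACKS:
        for eid, chrom, c, is_bound, _ in enhancers:
            amp = amp_bound if is_bound else amp_unbound
            vals = amp * bump_shape
            if cfg.noise_sd > 0:
                vals = vals + np.maximum(rng.normal(0.0, cfg.noise_sd, n_bins), 0.0)
            lo = c - TRACK_FLANK
            track_lines[name].extend(
                f"{chrom}\t{lo + k * TRACK_BIN}\t{lo + (k + 1) * TRACK_BIN}\t{v!r}"
                for k, v in enumerate(vals.tolist())
            )

    # --- DE tables: planted targets significant, everything else null
    de_rows = {"miRNA": [], "mRNA": []}
    for g in genes:
        key = "miRNA" if g.is_mirna else "mRNA"
        if g.gene_id in planted_de:
            de_rows[key].append(
                (g.gene_id, planted_de[g.gene_id], float(rng.uniform(0.001, 0.049)))
            )
        else:
            de_rows[key].append(
                (g.gene_id, float(rng.normal(0.0, 0.5)), float(rng.uniform(0.05, 1.0)))
            )

    # ------------------------------------------------------------------ write
    paths: dict[str, Path] = {}

    def bed7(rows, name):
        p = out / name
        with open(p, "w") as fh:
            for chrom, s, e, rid, expr in sorted(rows):
                fh.write(f"{chrom}\t{s}\t{e}\t{rid}\t0\t.\t{expr!r}\n")
        return p

    paths["cage"] = bed7(cage_rows, "cage_enhancers.bed")
    paths["groseq"] = bed7(groseq_rows, "groseq_enhancers.bed")

    paths["peaks"] = out / "p53_peaks.bed"
    with open(paths["peaks"], "w") as fh:
        for chrom, s, e in peaks:
            fh.write(f"{chrom}\t{s}\t{e}\n")

    paths["tads"] = out / "tads.bed"
    with open(paths["tads"], "w") as fh:
        for chrom, s, e in tads:
            fh.write(f"{chrom}\t{s}\t{e}\n")

    paths["contacts"] = out / "contacts.bedpe"
    write_bedpe(sorted(contacts, key=lambda c: (c.anchor1.chrom, c.anchor1.start,
                                                c.anchor2.chrom, c.anchor2.start)),
                paths["contacts"])

    paths["genes"] = out / "genes.tsv"
    write_gene_table(sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id)),
                     paths["genes"])

    for key, name in (("miRNA", "de_mirna.tsv"), ("mRNA", "de_mrna.tsv")):
        p = out / name
        pd.DataFrame(sorted(de_rows[key]),
                     columns=["feature_id", "log2fc", "q_value"]).to_csv(
            p, sep="\t", index=False, float_format=None)
        paths["de_mirna" if key == "miRNA" else "de_mrna"] = p

    manifest_rows = []
    for name, category in TRACKS:
        p = out / "tracks" / f"{name}.bedgraph"
        with open(p, "w") as fh:
            fh.write("\n".join(track_lines[name]) + "\n")
        manifest_rows.append((name, str(Path("tracks") / f"{name}.bedgraph"), category))
        paths[f"track_{name}"] = p
    paths["manifest"] = out / "tracks_manifest.tsv"
    pd.DataFrame(manifest_rows, columns=["track_name", "path", "category"]).to_csv(
        paths["manifest"], sep="\t", index=False)

    truth = SyntheticTruth(
        bound_ids=bound_ids,
        true_links=true_links,
        planted_amplitudes={"bound": amp_bound, "unbound": amp_unbound},
        planted_de=planted_de,
        amplitude_ratio=cfg.amplitude_ratio,
        expression_shift=cfg.expression_shift,
    )
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(truth.to_json() + "\n")
    paths["config"] = out / "config.json"
    paths["config"].write_text(
        json.dumps(dataclasses.asdict(cfg), indent=1, sort_keys=True) + "\n"
    )
    return paths, truth


# --------------------------------------------------------------------------
# packaged transcription of the published 26-link enhancer-miRNA table

def _table1_text() -> str:
    ref = importlib.resources.files("enhlink").joinpath("data/table1_links.tsv")
    return ref.read_text()


def load_table1(zero_based: bool = True) -> pd.DataFrame:
    """Load the packaged 26-row enhancer-miRNA link table.

    The file stores coordinates 1-based inclusive as printed; with
    ``zero_based=True`` (default) starts are shifted by -1 to the internal
    half-open convention.
    """
    from io import StringIO

    df = pd.read_csv(StringIO(_table1_text()), sep="\t", comment="#")
    if zero_based:
        df = df.assign(enhancer_start=df["enhancer_start"] - 1)
    return df


def make_table1_fixture(out_path: Optional[PathLike] = None) -> pd.DataFrame:
    """Emit the verbatim packaged link table (optionally writing it to a file)."""
    if out_path is not None:
        Path(out_path).write_text(_table1_text())
    return load_table1(zero_based=False)


def table1_links() -> list[TargetLink]:
    """The packaged table as :class:`TargetLink` records (0-based enhancer ids)."""
    links = []
    for row in load_table1(zero_based=True).itertuples(index=False):
        evidence = frozenset(
            name
            for name, flag in (
                ("distance", row.evidence_distance),
                ("tad", row.evidence_tad),
                ("contact", row.evidence_contact),
            )
            if flag
        )
        links.append(
            TargetLink(
                enhancer_id=f"{row.enhancer_chrom}:{row.enhancer_start}-{row.enhancer_end}",
                target_id=row.target_id,
                target_type=row.target_type,
                evidence=evidence,
                log2fc=float(row.log2fc),
            )
        )
    return links
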