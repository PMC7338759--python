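"""Differential-expression thresholds and set-overlap statistics.

DE model fitting happens upstream (the tables are inputs); this module
applies the significance thresholds — q-value strictly below 0.05 and
|log2 fold change| >= 1 by default — and provides the driver-gene overlap
fraction and a generic hypergeometric over-representation test for gene
sets.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "apply_de_thresholds",
    "overlap_fraction",
    "over_representation",
    "over_representation_batch",
]

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "not_significant"


def apply_de_thresholds(
    table: pd.DataFrame, q_max: float = 0.05, lfc_min: float = 1.0
) -> tuple[pd.DataFrame, int, int]:
    """Assign up/down/not_significant status and count the significant rows.

    A feature is ``up`` iff q < ``q_max`` (strict) and log2FC >= ``lfc_min``
    (inclusive); ``down`` iff q < ``q_max`` and log2FC <= -``lfc_min``.
    Returns ``(table with a status column, n_up, n_down)``; the significant
    set is exactly the up and down rows.
    """
    required = {"feature_id", "log2fc", "q_value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    q = table["q_value"].to_numpy(dtype=float)
    if np.any((q < 0) | (q > 1)) or np.any(np.isnan(q)):
        raise ValueError("q_values must lie in [0, 1]")
    lfc = table["log2fc"].to_numpy(dtype=float)
    sig = q < q_max
    up = sig & (lfc >= lfc_min)
    down = sig & (lfc <= -lfc_min)
    out = table.copy()
    out["status"] = np.where(up, STATUS_UP, np.where(down, STATUS_DOWN, STATUS_NS))
    return out, int(up.sum()), int(down.sum())


def significant_log2fc(table: pd.DataFrame, q_max: float = 0.05, lfc_min: float = 1.0) -> dict[str, float]:
    """Map feature_id -> log2fc for the significant rows only."""
    labelled, _, _ = apply_de_thresholds(table, q_max, lfc_min)
    keep = labelled[labelled["status"] != STATUS_NS]
    return dict(zip(keep["feature_id"], keep["log2fc"].astype(float)))


def overlap_fraction(set_a: Sequence[str], set_b: Sequence[str]) -> float:
    """|A intersection B| / |B|, with B the reference (e.g. driver) list.

    The denominator is the reference set B, so the value answers "what
    fraction of the reference is covered by A".  An empty reference yields
    0 with a warning.
    """
    b = set(set_b)
    if not b:
        warnings.warn("empty reference set; overlap fraction defined as 0", stacklevel=2)
        return 0.0
    return len(set(set_a) & b) / len(b)


def over_representation(
    hits: Sequence[str], universe: Sequence[str], gene_set: Sequence[str]
) -> tuple[float, float]:
    """One-sided hypergeometric over-representation of ``gene_set`` in ``hits``.

    ``hits`` must be drawn from ``universe``; the gene set is intersected
    with the universe first.  Returns ``(p_value, fold_enrichment)`` where
    fold = observed overlap / expected overlap under random draws; fold is 0
    when the overlap is 0, and NaN when the expected count is 0 (empty gene
    set after intersection).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    hit_set = set(hits)
    if not hit_set <= uni:
        raise ValueError("hits must be a subset of the universe")
    gset = set(gene_set) & uni
    N, K, n = len(uni), len(gset), len(hit_set)
    k = len(hit_set & gset)
    # P(X >= k) for X ~ Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    expected = n * K / N
    fold = (k / expected) if expected > 0 else float("nan")
    return min(p, 1.0), fold


def over_representation_batch(
    hits: Sequence[str],
    universe: Sequence[str],
    gene_sets: dict[str, Sequence[str]],
) -> pd.DataFrame:
    """Hypergeometric test per gene set with BH adjustment across sets.

    Returns a DataFrame (set_id, overlap, p_value, q_value, fold) ordered by
    p-value then set_id.
    """
    rows = []
    hit_set = set(hits)
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & set(universe)
        p, fold = over_representation(hits, universe, members)
        rows.append((set_id, len(hit_set & members), p, fold))
    df = pd.DataFrame(rows, columns=["set_id", "overlap", "p_value", "fold"])
    if len(df):
        _, qvals, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
        df["q_value"] = qvals
    else:
        df["q_value"] = []
    df = df[["set_id", "overlap", "p_value", "q_value", "fold"]]
    return df.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)
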