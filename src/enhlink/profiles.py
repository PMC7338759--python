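"""Signal metaprofiles around enhancer centers and class comparisons.

Windows of +/- ``flank`` bp (default 1 kb) are anchored on each enhancer's
center.  Per-track class comparisons report the ratio of mean signal on the
TF-bound class over the unbound class, with a two-sided Wilcoxon rank-sum
test on the per-region window means and Benjamini-Hochberg adjustment across
tracks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import Enhancer
from .core import center
from .tracks import SignalTrack

__all__ = [
    "ProfileMatrix",
    "ClassComparison",
    "RankedTracks",
    "extract_profile",
    "mean_signal_ratio",
    "compare_expression",
    "rank_tracks",
]


@dataclass
class ProfileMatrix:
    """Mean signal per (region, bin) around region centers.

    ``bin_edges`` are offsets relative to the center, from ``-flank`` to
    ``+flank`` inclusive (length ``n_bins + 1``); ``values`` has shape
    ``(n_regions, n_bins)``.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    region_ids: list[str]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def metaprofile(self) -> np.ndarray:
        """Per-bin mean across regions (the plotted aggregate curve)."""
        return self.values.mean(axis=0)


@dataclass
class ClassComparison:
    """Bound-vs-unbound summary for one signal track.

    ``ratio`` is ``mean_bound / mean_unbound`` (NaN when the unbound mean is
    zero); ``q_value`` is NaN until BH adjustment across tracks
    (:func:`rank_tracks`).
    """

    track_name: str
    mean_bound: float
    mean_unbound: float
    ratio: float
    p_value: float
    q_value: float = math.nan


@dataclass
class RankedTracks:
    """Tracks sorted by ratio (descending) with higher/lower/tied counts."""

    comparisons: list[ClassComparison]
    n_higher: int
    n_lower: int
    n_tied: int


def extract_profile(
    track: SignalTrack,
    regions: Sequence[Enhancer],
    flank: int = 1000,
    bin_width: int = 10,
) -> ProfileMatrix:
    """Bin the track in +/- ``flank`` bp windows centered on each region.

    Each cell is the mean per-base signal over that bin's bases; bases off
    the end of a chromosome (or uncovered by the track) read 0.  Regions on
    chromosomes absent from the track produce an all-zero row and a warning.
    """
    if flank <= 0 or bin_width <= 0 or flank % bin_width != 0:
        raise ValueError("flank must be a positive multiple of bin_width")
    n_bins = 2 * flank // bin_width
    edges = np.arange(-flank, flank + bin_width, bin_width)
    values = np.zeros((len(regions), n_bins))
    missing: set[str] = set()
    for i, region in enumerate(regions):
        chrom = region.interval.chrom
        if track and not track.has_chrom(chrom):
            missing.add(chrom)
            continue
        c = center(region.interval)
        for b in range(n_bins):
            lo = c - flank + b * bin_width
            values[i, b] = track.window_mean(chrom, lo, lo + bin_width)
    if missing:
        warnings.warn(
            f"regions on chromosomes absent from track: {sorted(missing)}; "
            "their profile rows are all zero",
            stacklevel=2,
        )
    ids = [r.interval.name or f"region_{i}" for i, r in enumerate(regions)]
    return ProfileMatrix(bin_edges=edges, values=values, region_ids=ids)


def _window_means(track: SignalTrack, regions: Sequence[Enhancer], flank: int) -> np.ndarray:
    out = np.empty(len(regions))
    for i, region in enumerate(regions):
        c = center(region.interval)
        out[i] = track.window_mean(region.interval.chrom, c - flank, c + flank)
    return out


def mean_signal_ratio(
    track: SignalTrack,
    bound: Sequence[Enhancer],
    unbound: Sequence[Enhancer],
    flank: int = 1000,
    track_name: str = "",
) -> ClassComparison:
    """Class mean signal in +/- ``flank`` windows and their ratio.

    The class mean is the grand mean over all (region, base) pairs; with
    equal-width windows this equals the mean of per-region means, which is
    what the rank-sum test is run on.  A zero unbound mean yields a NaN
    ratio (undefined rather than infinite).
    """
    if not bound or not unbound:
        raise ValueError("both enhancer classes must be non-empty")
    means_b = _window_means(track, bound, flank)
    means_u = _window_means(track, unbound, flank)
    mean_b, mean_u = float(means_b.mean()), float(means_u.mean())
    ratio = mean_b / mean_u if mean_u > 0 else math.nan
    p = compare_expression(means_b, means_u)
    return ClassComparison(track_name, mean_b, mean_u, ratio, p)


def compare_expression(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact enumeration when both samples have n <= 8 and there are no ties;
    otherwise the normal approximation with tie correction (no continuity
    correction, so identical samples give p = 1 exactly).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def rank_tracks(comparisons: Sequence[ClassComparison]) -> RankedTracks:
    """Sort tracks by ratio (descending) and BH-adjust p-values across tracks.

    Also counts tracks with ratio > 1 (higher on the bound class), < 1, and
    exactly 1 (tied).  NaN ratios sort last and count as tied.
    """
    ordered = sorted(
        comparisons,
        key=lambda c: (-(c.ratio) if not math.isnan(c.ratio) else math.inf, c.track_name),
    )
    pvals = [c.p_value for c in ordered]
    if pvals:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        qvals = []
    ordered = [replace(c, q_value=float(q)) for c, q in zip(ordered, qvals)]
    n_higher = sum(1 for c in ordered if not math.isnan(c.ratio) and c.ratio > 1)
    n_lower = sum(1 for c in ordered if not math.isnan(c.ratio) and c.ratio < 1)
    return RankedTracks(
        comparisons=ordered,
        n_higher=n_higher,
        n_lower=n_lower,
        n_tied=len(ordered) - n_higher - n_lower,
    )
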