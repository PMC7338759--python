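"""Piecewise-constant coverage tracks (bedGraph semantics).

A :class:`SignalTrack` stores, per chromosome, sorted non-overlapping
intervals each carrying a float value.  Positions not covered by any
interval read 0 — the bedGraph sparsity convention — and windows extending
past either end of a chromosome likewise read 0 over the uncovered bases.
"""

from __future__ import annotations

from typing import Iterable, Tuple

import numpy as np

__all__ = ["SignalTrack"]


class SignalTrack:
    """Per-chromosome piecewise-constant signal with fast window sums."""

    def __init__(self, entries: Iterable[Tuple[str, int, int, float]] = ()):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in entries:
            if not 0 <= start < end:
                raise ValueError(f"invalid track interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, float(value)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivals in per_chrom.items():
            ivals.sort()
            starts = np.array([s for s, _, _ in ivals], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivals], dtype=np.int64)
            values = np.array([v for _, _, v in ivals], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                bad = int(np.flatnonzero(starts[1:] < ends[:-1])[0])
                raise ValueError(
                    f"overlapping track intervals on {chrom} near "
                    f"{starts[bad + 1]}"
                )
            self._data[chrom] = (starts, ends, values)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._data)

    def __bool__(self) -> bool:  # empty track is falsy
        return bool(self._data)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._data

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base signal over ``[start, end)``; uncovered bases add 0.

        ``start`` may be negative (a window running off the chromosome
        start); those bases simply contribute 0.
        """
        if end <= start:
            raise ValueError("empty window")
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.dot(np.maximum(ov, 0), values[lo:hi]))

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base signal over ``[start, end)`` (denominator = width)."""
        return self.window_sum(chrom, start, end) / (end - start)

    def scaled(self, factor: float) -> "SignalTrack":
        """New track with every value multiplied by ``factor``."""
        out = SignalTrack()
        out._data = {
            chrom: (starts, ends, values * factor)
            for chrom, (starts, ends, values) in self._data.items()
        }
        return out

    def to_entries(self) -> list[tuple[str, int, int, float]]:
        rows = []
        for chrom in self.chromosomes:
            starts, ends, values = self._data[chrom]
            rows.extend(
                (chrom, int(s), int(e), float(v))
                for s, e, v in zip(starts, ends, values)
            )
        return rows
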