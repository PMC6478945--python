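"""Aggregation of per-target counts onto bin grids and cross-resolution
re-binning.

Apportionment is linear in overlap width: an input interval contributes to
each overlapping bin proportionally to the overlapping width, so total count
is conserved for intervals fully inside the grid.  Bins with no covering
input get NaN (an explicit missing marker), never 0 or an interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .genome import (BinGrid, DEFAULT_SCALES, GenomeLayout, GenomicInterval,
                     bait_grid, tile_genome)
from .track_io import TrackTable


@dataclass
class BinnedCounts:
    """Per-bin counts (and optional GC fraction) on one grid."""

    grid: BinGrid
    counts: np.ndarray
    gc: np.ndarray | None = None
    sample_id: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.grid):
            raise ValueError("counts length != bin count")
        finite = self.counts[~np.isnan(self.counts)]
        if np.any(finite < 0):
            raise ValueError("counts must be >= 0")
        if self.gc is not None:
            self.gc = np.asarray(self.gc, dtype=float)
            if len(self.gc) != len(self.grid):
                raise ValueError("gc length != bin count")

    def copy(self) -> "BinnedCounts":
        return BinnedCounts(self.grid, self.counts.copy(),
                            None if self.gc is None else self.gc.copy(),
                            self.sample_id, self.provenance)

    def to_track(self, kind: str = "counts") -> TrackTable:
        return TrackTable.from_arrays(
            self.grid.bins, self.counts, kind=kind, gc=self.gc,
            grid_label=self.grid.resolution_label, sample_id=self.sample_id,
            provenance=self.provenance)


class _GridIndex:
    """Per-chromosome sorted bin arrays for fast interval -> bin lookup."""

    def __init__(self, grid: BinGrid) -> None:
        self.offsets: dict[str, int] = {}
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        chrom = None
        buf_s: list[int] = []
        buf_e: list[int] = []
        off = 0
        for i, b in enumerate(grid.bins):
            if b.chrom != chrom:
                if chrom is not None:
                    self.starts[chrom] = np.array(buf_s)
                    self.ends[chrom] = np.array(buf_e)
                chrom = b.chrom
                self.offsets[chrom] = i
                buf_s, buf_e = [], []
            buf_s.append(b.start)
            buf_e.append(b.end)
        if chrom is not None:
            self.starts[chrom] = np.array(buf_s)
            self.ends[chrom] = np.array(buf_e)

    def overlapping(self, chrom: str, start: int, end: int):
        """Yield (global bin index, overlap width) for bins hitting [start, end)."""
        if chrom not in self.starts:
            return
        s, e = self.starts[chrom], self.ends[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        off = self.offsets[chrom]
        for j in range(lo, len(s)):
            if s[j] >= end:
                break
            w = min(e[j], end) - max(s[j], start)
            if w > 0:
                yield off + j, w


def aggregate_counts(intervals: TrackTable, grid: BinGrid) -> BinnedCounts:
    """Apportion interval counts to bins proportionally to overlap width.

    Per-bin GC is the overlap-width-weighted mean of contributing interval
    GC values (NaN where no contributor carries GC).
    """
    idx = _GridIndex(grid)
    counts = np.zeros(len(grid))
    gc_num = np.zeros(len(grid))
    gc_den = np.zeros(len(grid))
    df = intervals.df
    has_gc = df["gc"].notna().any()
    for row in df.itertuples(index=False):
        width = row.end - row.start
        for bin_i, w in idx.overlapping(row.chrom, int(row.start), int(row.end)):
            frac = w / width
            counts[bin_i] += row.N * frac
            if has_gc and not np.isnan(row.gc):
                gc_num[bin_i] += row.gc * w
                gc_den[bin_i] += w
    gc = None
    if has_gc:
        gc = np.full(len(grid), np.nan)
        covered = gc_den > 0
        gc[covered] = gc_num[covered] / gc_den[covered]
    return BinnedCounts(grid, counts, gc=gc, sample_id=intervals.sample_id,
                        provenance="aggregate_counts")


def rebin_values(fine: TrackTable, coarse: BinGrid) -> TrackTable:
    """Re-bin a value track onto a coarser grid.

    Each coarse bin gets the overlap-width-weighted mean of fine values
    covering it; re-binned sd follows the variance-of-weighted-mean rule
    sd^2 = sum(w_i * sd_i^2) / (sum w_i)^2.  Coarse bins with no covering
    fine value are NaN.  Only covered width enters the weighted mean, so
    gaps in the fine track do not dilute the result.
    """
    idx = _GridIndex(coarse)
    n = len(coarse)
    wsum = np.zeros(n)
    vsum = np.zeros(n)
    varsum = np.zeros(n)
    has_sd = fine.df["sd"].notna().any()
    for row in fine.df.itertuples(index=False):
        if np.isnan(row.N):
            continue
        for bin_i, w in idx.overlapping(row.chrom, int(row.start), int(row.end)):
            wsum[bin_i] += w
            vsum[bin_i] += w * row.N
            if has_sd and not np.isnan(row.sd):
                varsum[bin_i] += w * row.sd ** 2
    values = np.full(n, np.nan)
    covered = wsum > 0
    values[covered] = vsum[covered] / wsum[covered]
    sd = None
    if has_sd:
        sd = np.full(n, np.nan)
        sd[covered] = np.sqrt(varsum[covered]) / wsum[covered]
    return TrackTable.from_arrays(
        coarse.bins, values, kind="cn_bins", sd=sd,
        grid_label=coarse.resolution_label, sample_id=fine.sample_id,
        provenance=f"rebin<-{fine.grid_label}")


def build_all_scales(
    counts: TrackTable,
    layout: GenomeLayout,
    bait_targets: Iterable[GenomicInterval] | None = None,
    scales: Mapping[str, int] | None = None,
) -> dict[str, BinnedCounts]:
    """Aggregate one counts track at every configured display scale.

    Returns one :class:`BinnedCounts` per fixed-size scale plus, when bait
    targets are given, one at bait resolution labelled ``target``.
    """
    scales = dict(scales) if scales is not None else dict(DEFAULT_SCALES)
    if not scales and bait_targets is None:
        raise ValueError("no scales requested")
    out: dict[str, BinnedCounts] = {}
    for label, size in scales.items():
        grid = tile_genome(layout, size, resolution_label=label)
        out[label] = aggregate_counts(counts, grid)
    if bait_targets is not None:
        grid = bait_grid(bait_targets, layout)
        out["target"] = aggregate_counts(counts, grid)
    return out
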