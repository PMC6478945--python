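"""Numerical core: library scaling, GC correction, robust reference
construction, CN estimation, sample-vs-sample ratio mode and QC statistics.

The reference model uses the median for per-bin location and
1.4826 * MAD (the Gaussian consistency factor) for per-bin scale, which
keeps tumour samples in the reference cohort from biasing it.  Reported CN
error bars carry only the tested sample's contribution and therefore
underestimate the full SD of the CN; with enough reference samples they are
a good lower bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .binning import BinnedCounts
from .genome import BinGrid
from .track_io import TrackTable

logger = logging.getLogger(__name__)

MAD_CONSISTENCY = 1.4826

FLAG_NAMES = ("low_ref", "masked", "missing")


def robust_sd(x: np.ndarray, center: float | np.ndarray | None = None) -> float:
    """1.4826 * median absolute deviation."""
    x = np.asarray(x, dtype=float)
    if center is None:
        center = np.median(x)
    return MAD_CONSISTENCY * float(np.median(np.abs(x - center)))


def robust_cv(x: np.ndarray) -> float:
    """Robust coefficient of variation: 1.4826 * MAD / median.

    Computed over finite, nonzero entries; NaN (with a warning) when the
    median is zero or no entries remain.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x) & (x != 0)]
    if len(x) == 0:
        logger.warning("robust_cv: no usable values")
        return float("nan")
    med = float(np.median(x))
    if med == 0:
        logger.warning("robust_cv: median is zero; CV undefined")
        return float("nan")
    return robust_sd(x, med) / abs(med)


def _check_same_grid(a: BinGrid, b: BinGrid) -> None:
    if a.bins != b.bins:
        raise ValueError("grid mismatch: bin sets differ")


@dataclass
class ReferenceModel:
    """Per-bin robust location/scale built from selected reference samples."""

    grid: BinGrid
    ref_median: np.ndarray
    ref_sd: np.ndarray
    n_samples: int
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ref_median = np.asarray(self.ref_median, dtype=float)
        self.ref_sd = np.asarray(self.ref_sd, dtype=float)
        if self.n_samples != len(self.member_ids):
            raise ValueError("n_samples != number of member ids")
        if self.n_samples < 1:
            raise ValueError("reference needs at least one sample")
        finite = self.ref_sd[np.isfinite(self.ref_sd)]
        if np.any(finite < 0):
            raise ValueError("ref_sd must be >= 0")


@dataclass
class CNEstimate:
    """Per-bin linear copy number (diploid = 2) with error and flags."""

    grid: BinGrid
    cn: np.ndarray
    sd: np.ndarray
    flags: dict[str, np.ndarray] = field(default_factory=dict)
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.cn = np.asarray(self.cn, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        n = len(self.grid)
        for name in FLAG_NAMES:
            self.flags.setdefault(name, np.zeros(n, dtype=bool))
        ok = ~self.flags["missing"] & np.isfinite(self.cn)
        if np.any(self.cn[ok] < 0):
            raise ValueError("cn must be >= 0 where not missing")

    def copy(self) -> "CNEstimate":
        return CNEstimate(self.grid, self.cn.copy(), self.sd.copy(),
                          {k: v.copy() for k, v in self.flags.items()},
                          self.sample_id)

    def to_track(self) -> TrackTable:
        return TrackTable.from_arrays(
            self.grid.bins, self.cn, kind="cn_bins", sd=self.sd,
            grid_label=self.grid.resolution_label, sample_id=self.sample_id)


@dataclass
class QCSummary:
    """Robust CVs of raw counts, GC-corrected counts and called CN."""

    cv_raw: float
    cv_gc: float
    cv_cn: float
    resolution: str = ""
    split: dict = field(default_factory=dict)  # e.g. {"target": {...}, "offtarget": {...}}

    def as_dict(self) -> dict:
        d = {"resolution": self.resolution, "cv_raw": self.cv_raw,
             "cv_gc": self.cv_gc, "cv_cn": self.cv_cn}
        if self.split:
            d["split"] = self.split
        return d


# ----------------------------------------------------------------------


def library_scale_factor(counts: np.ndarray, ref_median: np.ndarray) -> float:
    """Median over usable bins of ref_median / counts."""
    counts = np.asarray(counts, dtype=float)
    ref = np.asarray(ref_median, dtype=float)
    ok = np.isfinite(counts) & np.isfinite(ref) & (counts > 0) & (ref > 0)
    if not ok.any():
        raise ValueError("cannot scale: no bins with positive counts and reference")
    return float(np.median(ref[ok] / counts[ok]))


def scale_library(counts: BinnedCounts, reference: ReferenceModel) -> BinnedCounts:
    """Scale a sample onto the reference's library size.

    The factor s is the median of ref_median_i / counts_i over bins where
    both are positive; it is recorded in the output's provenance.
    """
    _check_same_grid(counts.grid, reference.grid)
    s = library_scale_factor(counts.counts, reference.ref_median)
    out = counts.copy()
    out.counts = counts.counts * s
    out.provenance = (counts.provenance + ";" if counts.provenance else "") + \
        f"scale_library:s={s:.6g}"
    return out


# ----------------------------------------------------------------------
# GC correction: stratified running-median, isolated so an alternative
# (e.g. loess) can be swapped in.

GC_STRATUM_WIDTH = 0.02


def gc_correct(counts: BinnedCounts,
               stratum_width: float = GC_STRATUM_WIDTH,
               min_gc_fraction: float = 0.9,
               bias_source: BinnedCounts | None = None) -> BinnedCounts:
    """Remove GC-dependent coverage bias.

    The bias curve f(gc) is the median count within ``stratum_width``-wide GC
    strata, smoothed by a running median over strata and linearly
    interpolated at each bin's GC.  Corrected = count * global_median / f(gc).
    Bins without GC pass through unchanged and are flagged via the
    ``gc_uncorrected`` attribute of the returned object.

    With ``bias_source`` (e.g. the per-bin cohort median) the curve is
    estimated from that track instead of from the sample itself, which keeps
    large planted/true CNVs from being absorbed into the bias estimate.
    """
    x = counts.counts
    if not np.any(x[np.isfinite(x)] > 0):
        raise ValueError("gc_correct: all counts are zero")
    if counts.gc is None:
        raise ValueError("gc_correct: no GC values on this track")
    gc = counts.gc
    nonzero = np.isfinite(x) & (x > 0)
    has_gc = np.isfinite(gc)
    if nonzero.sum() and (has_gc & nonzero).sum() / nonzero.sum() < min_gc_fraction:
        raise ValueError(
            f"gc_correct: GC present for < {min_gc_fraction:.0%} of nonzero bins")

    src = x if bias_source is None else bias_source.counts
    usable = np.isfinite(src) & (src > 0) & has_gc
    if not usable.any():
        raise ValueError("gc_correct: no usable bins in bias source")
    strata = np.floor(gc[usable] / stratum_width).astype(int)
    knot_x, knot_y = [], []
    for s in np.unique(strata):
        sel = strata == s
        knot_x.append(float(np.median(gc[usable][sel])))
        knot_y.append(float(np.median(src[usable][sel])))
    knot_x = np.asarray(knot_x)
    knot_y = np.asarray(knot_y)
    order = np.argsort(knot_x)
    knot_x, knot_y = knot_x[order], knot_y[order]
    # running median over strata (window 3, endpoints kept)
    if len(knot_y) >= 3:
        sm = knot_y.copy()
        sm[1:-1] = np.median(
            np.column_stack([knot_y[:-2], knot_y[1:-1], knot_y[2:]]), axis=1)
        knot_y = sm
    global_median = float(np.median(src[usable]))
    f = np.interp(gc, knot_x, knot_y)
    factor = np.ones_like(x)
    corr = has_gc & (f > 0)
    factor[corr] = global_median / f[corr]
    out = counts.copy()
    out.counts = x * factor
    out.provenance = (counts.provenance + ";" if counts.provenance else "") + "gc_correct"
    out.gc_uncorrected = ~corr
    return out


# ----------------------------------------------------------------------


def build_reference(samples: Sequence[BinnedCounts],
                    grid: BinGrid | None = None) -> ReferenceModel:
    """Build the per-bin median/MAD reference from a sample cohort.

    Each sample is first normalized to the cohort in one pass: scaled so
    that its median ratio to the per-bin cross-sample median is 1.  Then
    ref_median is the per-bin median of normalized counts and ref_sd is
    1.4826 * the per-bin median absolute deviation.  With a single sample
    ref_sd is undefined and set missing (NaN).
    """
    if not samples:
        raise ValueError("build_reference: need at least one sample")
    if grid is None:
        grid = samples[0].grid
    for s in samples:
        _check_same_grid(s.grid, grid)
    mat = np.vstack([s.counts for s in samples])
    if len(samples) > 1:
        pseudo = np.median(mat, axis=0)
        for i in range(mat.shape[0]):
            s = library_scale_factor(mat[i], pseudo)
            mat[i] = mat[i] * s
    ref_median = np.median(mat, axis=0)
    if len(samples) == 1:
        ref_sd = np.full(len(grid), np.nan)
    else:
        ref_sd = MAD_CONSISTENCY * np.median(np.abs(mat - ref_median), axis=0)
    return ReferenceModel(grid=grid, ref_median=ref_median, ref_sd=ref_sd,
                          n_samples=len(samples),
                          member_ids=[s.sample_id or f"sample{i}"
                                      for i, s in enumerate(samples)])


DEFAULT_MIN_REF_READS = 10.0
DEFAULT_MIN_REF_FRACTION = 0.01


def _low_ref_floor(reference: ReferenceModel,
                   min_reads: float, min_fraction: float) -> np.ndarray:
    """Per-bin floor: max(min_reads, min_fraction * chromosome median)."""
    floor = np.full(len(reference.grid), min_reads)
    for chrom, sl in reference.grid.chrom_slices().items():
        med = np.nanmedian(reference.ref_median[sl])
        if np.isfinite(med):
            floor[sl] = max(min_reads, min_fraction * med)
    return floor


def estimate_cn(sample: BinnedCounts, reference: ReferenceModel,
                ploidy: float = 2.0,
                ploidy_overrides: Mapping[str, float] | None = None,
                min_ref_reads: float = DEFAULT_MIN_REF_READS,
                min_ref_fraction: float = DEFAULT_MIN_REF_FRACTION) -> CNEstimate:
    """Estimate per-bin copy number against the reference.

    cn_i = ploidy * x_i / ref_median_i where the reference is above the
    low-coverage floor; sd_i = ploidy * ref_sd_i / ref_median_i (the tested
    sample's contribution only).  Low-reference bins are flagged ``low_ref``
    and set missing rather than reported with an exploding ratio.
    The sample is expected to be library-scaled and GC-corrected already.
    """
    _check_same_grid(sample.grid, reference.grid)
    n = len(reference.grid)
    pl = np.full(n, float(ploidy))
    if ploidy_overrides:
        for chrom, sl in reference.grid.chrom_slices().items():
            if chrom in ploidy_overrides:
                pl[sl] = float(ploidy_overrides[chrom])
    floor = _low_ref_floor(reference, min_ref_reads, min_ref_fraction)
    usable = np.isfinite(reference.ref_median) & (reference.ref_median > floor)
    cn = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    cn[usable] = pl[usable] * sample.counts[usable] / reference.ref_median[usable]
    sd[usable] = pl[usable] * reference.ref_sd[usable] / reference.ref_median[usable]
    flags = {
        "low_ref": ~usable,
        "masked": np.zeros(n, dtype=bool),
        "missing": ~usable | ~np.isfinite(cn),
    }
    return CNEstimate(grid=reference.grid, cn=cn, sd=sd, flags=flags,
                      sample_id=sample.sample_id)


# ----------------------------------------------------------------------


def ratio_mode(sample_a: CNEstimate | BinnedCounts,
               sample_b: CNEstimate | BinnedCounts,
               floor: float | None = None) -> TrackTable:
    """Sample-vs-sample ratio with b as the denominator.

    Works on CN estimates and on (scaled) count tracks alike — the latter
    supports ratio views of any counts-based data such as RNA-seq.
    Bins where the denominator is below the floor are missing (NaN).
    """
    a_vals, a_grid, a_id = _values_of(sample_a)
    b_vals, b_grid, _ = _values_of(sample_b)
    _check_same_grid(a_grid, b_grid)
    if floor is None:
        pos = b_vals[np.isfinite(b_vals) & (b_vals > 0)]
        floor = 0.01 * float(np.median(pos)) if len(pos) else 0.0
    ratio = np.full(len(a_grid), np.nan)
    ok = np.isfinite(a_vals) & np.isfinite(b_vals) & (b_vals > floor)
    ratio[ok] = a_vals[ok] / b_vals[ok]
    return TrackTable.from_arrays(
        a_grid.bins, ratio, kind="cn_bins",
        grid_label=a_grid.resolution_label, sample_id=a_id,
        provenance="ratio_mode")


def _values_of(obj: CNEstimate | BinnedCounts):
    if isinstance(obj, CNEstimate):
        vals = obj.cn.copy()
        vals[obj.flags["missing"]] = np.nan
        return vals, obj.grid, obj.sample_id
    return obj.counts, obj.grid, obj.sample_id


# ----------------------------------------------------------------------


def qc_summary(raw: BinnedCounts, corrected: BinnedCounts, cn: CNEstimate,
               targeted_mask: np.ndarray | None = None,
               resolution: str = "") -> QCSummary:
    """Robust CVs for raw counts, corrected counts and called CN.

    With a targeted mask, the three CVs are additionally reported separately
    for targeted and untargeted bins.
    """
    _check_same_grid(raw.grid, corrected.grid)
    _check_same_grid(raw.grid, cn.grid)
    cn_vals = cn.cn.copy()
    cn_vals[cn.flags["missing"]] = np.nan

    def triple(mask=None):
        def sel(v):
            return v if mask is None else v[mask]
        return {
            "cv_raw": robust_cv(sel(raw.counts)),
            "cv_gc": robust_cv(sel(corrected.counts)),
            "cv_cn": robust_cv(sel(cn_vals)),
        }

    whole = triple()
    split = {}
    if targeted_mask is not None:
        targeted_mask = np.asarray(targeted_mask, dtype=bool)
        split = {"target": triple(targeted_mask),
                 "offtarget": triple(~targeted_mask)}
    return QCSummary(cv_raw=whole["cv_raw"], cv_gc=whole["cv_gc"],
                     cv_cn=whole["cv_cn"], resolution=resolution, split=split)
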