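"""Deterministic static rendering of the three-panel multi-scale CN view.

The interactive browser's click-driven navigation is replaced by a
declarative :class:`ViewSpec`: panel selections and gene zooms are stated up
front and the figure is written once.  SVG output is byte-stable across runs
on identical inputs (fixed hashsalt, no timestamp metadata).
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Rectangle

from .filters import flag_overflow
from .genome import GenomeLayout, GenomicInterval
from .track_io import BreakpointRecord, TrackTable

matplotlib.rcParams["svg.hashsalt"] = "cnkit"

#: Default palette (documented, fixed).
PALETTE = {
    "points": "#2c5f8a",
    "overflow": "#c0392b",
    "error": "#9bb7cc",
    "segment": "#7d3c98",
    "breakpoint": "#1a7a4a",
    "baf": "#b9770e",
    "exon": "#444444",
    "target": "#888888",
    "stains": {
        "gneg": "#ffffff", "gpos25": "#c8c8c8", "gpos50": "#969696",
        "gpos75": "#646464", "gpos100": "#323232", "acen": "#cc4444",
        "gvar": "#dddddd", "stalk": "#8888aa",
    },
}

GAP_VALUE = np.nan  # missing bins render as gaps, never interpolated


@dataclass
class ViewSpec:
    """Declarative description of the three-panel multi-scale view."""

    panels: list[str] = field(default_factory=lambda: ["genome", "arm", "region"])
    selection: dict[str, GenomicInterval] = field(default_factory=dict)
    gene_zoom: str | None = None
    ymax: float = 6.0
    overlays: set[str] = field(default_factory=lambda: {"error_bars", "targeted_track"})
    output: str = "view.svg"
    format: str = "svg"

    def __post_init__(self) -> None:
        if not self.panels:
            raise ValueError("panels must be non-empty")
        if self.ymax <= 0:
            raise ValueError("ymax must be > 0")


def gene_zoom(annotation: TrackTable, gene: str, pad_fraction: float = 0.05
              ) -> GenomicInterval:
    """Interval spanning a gene's exons, padded by 5% of the span each side."""
    df = annotation.df
    genes = df["gene"] if "gene" in df.columns else df["label"].str.split("|").str[0]
    hits = df[genes == gene]
    if hits.empty:
        near = difflib.get_close_matches(gene, sorted(set(genes)), n=5)
        hint = f"; near matches: {', '.join(near)}" if near else ""
        raise KeyError(f"unknown gene {gene!r}{hint}")
    chrom = hits["chrom"].iloc[0]
    lo, hi = int(hits["start"].min()), int(hits["end"].max())
    pad = int(round((hi - lo) * pad_fraction))
    return GenomicInterval(chrom, max(0, lo - pad), hi + pad)


def feature_report(track: TrackTable, selection: GenomicInterval,
                   ymax: float | None = None) -> tuple[pd.DataFrame, float]:
    """All records overlapping the selection, plus the median-N summary.

    The returned frame carries N, sd, gc, label and (when ``ymax`` is given)
    an ``overflow`` column; the summary is the median N over the selection
    (NaN when nothing overlaps).
    """
    df = track.df
    m = ((df["chrom"] == selection.chrom)
         & (df["start"] < selection.end)
         & (df["end"] > selection.start))
    out = df[m].reset_index(drop=True)
    if ymax is not None:
        out = out.assign(overflow=flag_overflow(out["N"].to_numpy(), ymax))
    vals = out["N"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    summary = float(np.median(vals)) if len(vals) else float("nan")
    return out, summary


def _track_xy(track: TrackTable, layout: GenomeLayout,
              window: GenomicInterval | None):
    df = track.df
    if window is not None:
        m = ((df["chrom"] == window.chrom)
             & (df["start"] < window.end) & (df["end"] > window.start))
        df = df[m]
        x = ((df["start"] + df["end"]) / 2.0).to_numpy(dtype=float)
    else:
        x = np.array([layout.locate(c, (s + e) // 2)
                      for c, s, e in zip(df["chrom"], df["start"], df["end"])],
                     dtype=float)
    return x, df["N"].to_numpy(dtype=float), df["sd"].to_numpy(dtype=float)


def _draw_panel(ax, track: TrackTable, layout: GenomeLayout, spec: ViewSpec,
                window: GenomicInterval | None, title: str) -> int:
    x, y, sd = _track_xy(track, layout, window)
    over = np.isfinite(y) & (y > spec.ymax)
    shown = np.where(over, spec.ymax, y)
    if "error_bars" in spec.overlays and np.isfinite(sd).any():
        ax.errorbar(x, shown, yerr=np.where(np.isfinite(sd), sd, 0.0),
                    fmt="none", ecolor=PALETTE["error"], elinewidth=0.6, zorder=1)
    ax.plot(x, shown, ".", ms=3, color=PALETTE["points"], zorder=2)
    if over.any():
        ax.plot(x[over], np.full(over.sum(), spec.ymax), "v",
                ms=6, color=PALETTE["overflow"], zorder=3)
    ax.axhline(2.0, color="#bbbbbb", lw=0.6, zorder=0)
    ax.set_ylim(0, spec.ymax * 1.05)
    ax.set_ylabel("CN")
    ax.set_title(title, fontsize=9, loc="left")
    if window is not None:
        ax.set_xlim(window.start, window.end)
    else:
        ax.set_xlim(0, layout.total_length)
        for c in layout.chromosomes[1:]:
            ax.axvline(layout.genome_offset[c.name], color="#dddddd", lw=0.5)
        mids = [layout.genome_offset[c.name] + c.length / 2
                for c in layout.chromosomes]
        ax.set_xticks(mids)
        ax.set_xticklabels([c.name for c in layout.chromosomes], fontsize=6)
    return int(over.sum())


def _draw_ideogram(ax, layout: GenomeLayout) -> None:
    for band in layout.cytobands:
        iv = band.interval
        x0 = layout.locate(iv.chrom, iv.start)
        color = PALETTE["stains"].get(band.stain, "#eeeeee")
        ax.add_patch(Rectangle((x0, 0), iv.width, 1, facecolor=color,
                               edgecolor="#999999", lw=0.3))
    ax.set_xlim(0, layout.total_length)
    ax.set_ylim(0, 1)
    ax.set_yticks([])
    ax.set_xticks([])


def _draw_annotation(ax, annotation: TrackTable, window: GenomicInterval) -> None:
    df = annotation.df
    m = ((df["chrom"] == window.chrom)
         & (df["start"] < window.end) & (df["end"] > window.start))
    for row in df[m].itertuples(index=False):
        ax.add_patch(Rectangle((row.start, -0.25), row.end - row.start, 0.18,
                               facecolor=PALETTE["exon"], clip_on=False))


def _draw_segments(ax, segments: TrackTable, window: GenomicInterval | None,
                   layout: GenomeLayout, ymax: float) -> None:
    df = segments.df
    if window is not None:
        m = ((df["chrom"] == window.chrom)
             & (df["start"] < window.end) & (df["end"] > window.start))
        df = df[m]
    for row in df.itertuples(index=False):
        if window is None:
            x0 = layout.locate(row.chrom, int(row.start))
            x1 = layout.locate(row.chrom, int(row.end))
        else:
            x0, x1 = row.start, row.end
        ax.hlines(min(row.N, ymax), x0, x1, color=PALETTE["segment"],
                  lw=1.5, zorder=4)


def _draw_breakpoints(ax, breakpoints: Sequence[BreakpointRecord],
                      window: GenomicInterval, ymax: float) -> None:
    for bp in breakpoints:
        for end, mate in ((bp.end1, bp.end2), (bp.end2, bp.end1)):
            if end.chrom != window.chrom:
                continue
            if not (window.start < end.end and end.start < window.end):
                continue
            x = (end.start + end.end) / 2
            intra = mate.chrom == end.chrom
            ax.vlines(x, 0, ymax if intra else ymax / 2,
                      color=PALETTE["breakpoint"], lw=1.0, linestyles="--")
            if not intra:
                ax.annotate(f"->{mate.chrom}", (x, ymax / 2), fontsize=6,
                            color=PALETTE["breakpoint"])


def render_view(
    tracks: Mapping[str, TrackTable],
    layout: GenomeLayout,
    spec: ViewSpec,
    annotation: TrackTable | None = None,
    segments: TrackTable | None = None,
    breakpoints: Sequence[BreakpointRecord] = (),
    baf: TrackTable | None = None,
    target_track: TrackTable | None = None,
) -> pd.DataFrame:
    """Render the stacked multi-scale view and return the feature report.

    ``tracks`` maps resolution labels to CN tracks; each requested panel must
    be present.  The report covers the records of the last (detail) panel's
    window, including overflow flags, so every drawn overflow triangle is
    accountable to exactly one reported bin.
    """
    for label in spec.panels:
        if label not in tracks:
            raise KeyError(f"resolution {label!r} missing from supplied tracks "
                           f"(have: {', '.join(sorted(tracks))})")

    n_panels = len(spec.panels)
    has_ideo = bool(layout.cytobands)
    heights = [1.0] * n_panels
    if has_ideo:
        heights.insert(1, 0.12)
    fig, axes = plt.subplots(
        len(heights), 1, figsize=(10, 2.2 * n_panels + 0.5),
        gridspec_kw={"height_ratios": heights})
    axes = np.atleast_1d(axes)

    # resolve per-panel windows
    windows: list[GenomicInterval | None] = []
    for i, label in enumerate(spec.panels):
        win = spec.selection.get(label)
        if i == 0 and label == "genome":
            win = win  # genome panel defaults to the whole axis
        elif win is None and windows and windows[-1] is not None:
            win = windows[-1]
        windows.append(win)
    if spec.gene_zoom is not None:
        if annotation is None:
            raise ValueError("gene_zoom requested but no annotation provided")
        windows[-1] = gene_zoom(annotation, spec.gene_zoom)

    ax_iter = iter(axes)
    report = pd.DataFrame()
    for i, label in enumerate(spec.panels):
        ax = next(ax_iter)
        window = windows[i]
        title = label if window is None else f"{label}  {window}"
        _draw_panel(ax, tracks[label], layout, spec, window, title)
        if i == 0 and has_ideo:
            _draw_ideogram(next(ax_iter), layout)
        if window is not None:
            if segments is not None and "segments" in spec.overlays:
                _draw_segments(ax, segments, window, layout, spec.ymax)
            if breakpoints and "breakpoints" in spec.overlays:
                _draw_breakpoints(ax, breakpoints, window, spec.ymax)
            if baf is not None and "baf" in spec.overlays:
                bx, by, _ = _track_xy(baf, layout, window)
                ax.plot(bx, by * spec.ymax, "x", ms=3, color=PALETTE["baf"])
            if i == n_panels - 1:
                if annotation is not None:
                    _draw_annotation(ax, annotation, window)
                if (target_track is not None
                        and "targeted_track" in spec.overlays):
                    tx, ty, _ = _track_xy(target_track, layout, window)
                    shown = np.minimum(ty, spec.ymax)
                    ax.plot(tx, shown, "s", ms=2.5, mfc="none",
                            color=PALETTE["target"], zorder=2)
        elif segments is not None and "segments" in spec.overlays:
            _draw_segments(ax, segments, None, layout, spec.ymax)

    # feature report for the detail panel
    detail_label = spec.panels[-1]
    detail_window = windows[-1]
    report_track = (target_track
                    if target_track is not None and "targeted_track" in spec.overlays
                    else tracks[detail_label])
    if detail_window is not None:
        report, _ = feature_report(report_track, detail_window, ymax=spec.ymax)
    else:
        report = report_track.df.assign(
            overflow=flag_overflow(report_track.df["N"].to_numpy(), spec.ymax))

    fig.tight_layout()
    out = Path(spec.output)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, format=spec.format, metadata=_stable_metadata(spec.format))
    plt.close(fig)
    return report


def _stable_metadata(fmt: str) -> dict | None:
    if fmt == "svg":
        return {"Date": None}
    if fmt == "pdf":
        return {"CreationDate": None}
    return None
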