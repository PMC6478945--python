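"""Synthetic cohorts: reference samples plus test samples with planted CNVs,
a smooth GC-bias field and Poisson (optionally overdispersed) noise.

The expected count of a bin is

    mean_depth * (CN_eff / 2) * exp(gc_bias_strength * (gc - 0.5))

with CN_eff = 2 * (1 - f) + CN * f for a planted segment of copy number CN
at cellular fraction f.  Everything is driven by one integer seed, so a
fixed scenario reproduces byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import copy_number as cnum
from .binning import BinnedCounts, aggregate_counts
from .genome import (BinGrid, GenomeLayout, GenomicInterval, bait_grid,
                     hg19_layout, tile_genome, toy_layout)
from .track_io import TrackTable


@dataclass(frozen=True)
class CNVSegment:
    interval: GenomicInterval
    cn: float
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("cellular fraction must be in (0, 1]")
        if self.cn < 0:
            raise ValueError("cn must be >= 0")

    @property
    def cn_eff(self) -> float:
        return 2.0 * (1.0 - self.fraction) + self.cn * self.fraction


@dataclass
class SimScenario:
    """A fully specified simulation: layout, targets, noise and truth."""

    name: str
    layout: GenomeLayout
    mean_depth: float
    seed: int
    targets: list[GenomicInterval] | None = None  # None => whole-genome bins
    wgs_bin_size: int = 50_000
    gc_bias_strength: float = 0.0
    cnv_segments: list[CNVSegment] = field(default_factory=list)
    n_reference: int = 12
    overdispersion: float = 0.0  # extra-Poisson variance knob (FFPE-like noise)
    depth_jitter: float = 0.1   # per-sample lognormal library-size sd

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        for seg in self.cnv_segments:
            self.layout.validate_interval(seg.interval)

    def grid(self) -> BinGrid:
        if self.targets is not None:
            return bait_grid(self.targets, self.layout)
        return tile_genome(self.layout, self.wgs_bin_size, resolution_label="sim")


def gc_field(layout: GenomeLayout, intervals: Sequence[GenomicInterval]) -> np.ndarray:
    """Smooth deterministic GC fraction along the genome, clipped to [0.25, 0.75]."""
    out = np.empty(len(intervals))
    for i, iv in enumerate(intervals):
        mid = layout.locate(iv.chrom, (iv.start + iv.end) // 2)
        rank = layout.chrom_rank(iv.chrom)
        gc = (0.5
              + 0.12 * np.sin(2 * np.pi * mid / 7.3e6 + 0.9 * rank)
              + 0.08 * np.sin(2 * np.pi * mid / 1.1e6 + 2.1 * rank))
        out[i] = np.clip(gc, 0.25, 0.75)
    return out


def effective_cn(intervals: Sequence[GenomicInterval],
                 segments: Sequence[CNVSegment]) -> np.ndarray:
    """Per-interval effective CN: 2 plus overlap-weighted planted deviations."""
    cn = np.full(len(intervals), 2.0)
    for i, iv in enumerate(intervals):
        for seg in segments:
            w = iv.overlap_width(seg.interval)
            if w:
                cn[i] += (seg.cn_eff - 2.0) * (w / iv.width)
    return cn


def expected_counts(scn: SimScenario, grid: BinGrid,
                    segments: Sequence[CNVSegment]) -> tuple[np.ndarray, np.ndarray]:
    """(expected counts, gc) for one sample on the scenario grid."""
    gc = gc_field(scn.layout, grid.bins)
    cn_eff = effective_cn(grid.bins, segments)
    mu = scn.mean_depth * (cn_eff / 2.0) * np.exp(
        scn.gc_bias_strength * (gc - 0.5))
    return mu, gc


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 overdispersion: float) -> np.ndarray:
    if overdispersion > 0:
        mu = mu * rng.gamma(shape=1.0 / overdispersion,
                            scale=overdispersion, size=len(mu))
    return rng.poisson(mu).astype(float)


def simulate_cohort(scn: SimScenario) -> tuple[list[TrackTable], pd.DataFrame]:
    """Simulate reference samples plus one test sample carrying the CNVs.

    Returns the per-interval counts tables (references first, test sample
    last, id ``test``) and the truth table of planted segments.
    """
    rng = np.random.default_rng(scn.seed)
    grid = scn.grid()
    tables: list[TrackTable] = []
    mu_ref, gc = expected_counts(scn, grid, segments=[])
    for i in range(scn.n_reference):
        depth = float(np.exp(rng.normal(0.0, scn.depth_jitter)))
        counts = _draw_counts(rng, mu_ref * depth, scn.overdispersion)
        tables.append(TrackTable.from_arrays(
            grid.bins, counts, kind="counts", gc=gc,
            grid_label=grid.resolution_label,
            sample_id=f"ref{i + 1:02d}", provenance=f"sim:{scn.name}"))
    mu_test, _ = expected_counts(scn, grid, segments=scn.cnv_segments)
    depth = float(np.exp(rng.normal(0.0, scn.depth_jitter)))
    counts = _draw_counts(rng, mu_test * depth, scn.overdispersion)
    tables.append(TrackTable.from_arrays(
        grid.bins, counts, kind="counts", gc=gc,
        grid_label=grid.resolution_label,
        sample_id="test", provenance=f"sim:{scn.name}"))
    truth = pd.DataFrame({
        "chrom": [s.interval.chrom for s in scn.cnv_segments],
        "start": [s.interval.start for s in scn.cnv_segments],
        "end": [s.interval.end for s in scn.cnv_segments],
        "true_cn": [s.cn for s in scn.cnv_segments],
        "fraction": [s.fraction for s in scn.cnv_segments],
    })
    return tables, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ----------------------------------------------------------------------
# toy targeted panel


def toy_panel(layout: GenomeLayout, genes_per_chrom: int = 4,
              exons_per_gene: int = 10, exon_size: int = 150,
              exon_spacing: int = 2_000) -> tuple[list[GenomicInterval], TrackTable]:
    """A small synthetic capture panel: evenly spaced genes of equal exons.

    Returns (bait intervals, exon-level annotation track).  Gene names are
    ``G<chrom>_<i>``; transcripts ``T<gene>.1``.
    """
    baits: list[GenomicInterval] = []
    rows = []
    for c in layout.chromosomes:
        gene_span = exons_per_gene * exon_spacing
        step = (c.length - 2 * gene_span) // max(genes_per_chrom, 1)
        for g in range(genes_per_chrom):
            gstart = gene_span + g * step
            gene = f"G{c.name}_{g + 1}"
            tx = f"T{gene}.1"
            for e in range(exons_per_gene):
                s = gstart + e * exon_spacing
                iv = GenomicInterval(c.name, s, s + exon_size)
                baits.append(iv)
                num = e + 1
                rows.append((c.name, s, s + exon_size, float(num),
                             f"{gene}|{tx}|exon{num}", gene, tx, "+"))
    ann = pd.DataFrame(rows, columns=["chrom", "start", "end", "N", "label",
                                      "gene", "transcript", "strand"])
    return baits, TrackTable(ann, kind="annotation", layout=layout,
                             provenance="toy_panel")


# ----------------------------------------------------------------------
# presets emulating the four case-study regimes


def scenario_presets() -> dict[str, SimScenario]:
    """Four named scenarios with documented seeds.

    * ``germline_exon_del`` — targeted panel, one clonal single-exon
      heterozygous deletion.
    * ``hyperdiploid`` — scaled whole-genome bins; trisomies of chromosomes
      3, 5, 7, 9, 11, 15, 19 and 21, monosomy 13, plus a focal 17p deletion.
    * ``ctdna_focal_amp`` — low tumour fraction with a 20-copy focal
      amplification and a clonal-scale focal deletion.
    * ``lowpass_wgs`` — shallow whole-genome coverage with a focal
      amplification on 17q and a 1q-like arm gain.
    """
    presets: dict[str, SimScenario] = {}

    toy = toy_layout(n_chrom=3, length=10_000_000)
    baits, ann = toy_panel(toy)
    # exon 5 of gene G2_2 on chromosome 2: single-bait heterozygous loss
    del_exon = next(iv for iv, lab in zip(baits, ann.df["label"])
                    if lab == "G2_2|TG2_2.1|exon5")
    presets["germline_exon_del"] = SimScenario(
        name="germline_exon_del", layout=toy, targets=baits,
        mean_depth=500.0, gc_bias_strength=0.8, seed=11,
        cnv_segments=[CNVSegment(del_exon, cn=1.0, fraction=1.0)],
        n_reference=12)

    hg = hg19_layout(divisor=100)  # scaled genome for fast runs

    def span(chrom: str, a: float = 0.0, b: float = 1.0) -> GenomicInterval:
        ln = hg.chromosome(chrom).length
        return GenomicInterval(chrom, int(a * ln), int(b * ln))

    gains = [CNVSegment(span(c), cn=3.0, fraction=0.8)
             for c in ("3", "5", "7", "9", "11", "15", "19", "21")]
    hyper = gains + [
        CNVSegment(span("13"), cn=1.0, fraction=0.8),
        # focal deletion on 17p (TP53-locus scale; spans one native bin)
        CNVSegment(GenomicInterval("17", 50_000, 100_000), cn=1.0, fraction=0.8),
    ]
    presets["hyperdiploid"] = SimScenario(
        name="hyperdiploid", layout=hg, targets=None, wgs_bin_size=50_000,
        mean_depth=500.0, gc_bias_strength=0.6, seed=4,
        cnv_segments=hyper, n_reference=12)

    ctdna = [
        CNVSegment(GenomicInterval("12", 550_000, 700_000), cn=20.0, fraction=0.25),
        CNVSegment(GenomicInterval("17", 60_000, 90_000), cn=0.0, fraction=0.5),
    ]
    presets["ctdna_focal_amp"] = SimScenario(
        name="ctdna_focal_amp", layout=hg, targets=None, wgs_bin_size=25_000,
        mean_depth=800.0, gc_bias_strength=0.4, seed=5,
        cnv_segments=ctdna, n_reference=12)

    lowpass = [
        CNVSegment(GenomicInterval("17", 650_000, 720_000), cn=8.0, fraction=1.0),
        CNVSegment(span("1", 0.5, 1.0), cn=3.0, fraction=1.0),
    ]
    presets["lowpass_wgs"] = SimScenario(
        name="lowpass_wgs", layout=hg, targets=None, wgs_bin_size=50_000,
        mean_depth=30.0, gc_bias_strength=0.5, seed=6,
        cnv_segments=lowpass, n_reference=10)

    return presets


# ----------------------------------------------------------------------
# end-to-end pipeline on a scenario (used by CLI, tests and acceptance)


@dataclass
class ScenarioResult:
    scenario: SimScenario
    grid: BinGrid
    reference: cnum.ReferenceModel
    cn: cnum.CNEstimate
    raw: BinnedCounts
    corrected: BinnedCounts
    truth: pd.DataFrame
    tables: list[TrackTable]


def run_scenario(scn: SimScenario) -> ScenarioResult:
    """Simulate a cohort and run the full estimation pipeline on the test
    sample at the scenario's native resolution."""
    tables, truth = simulate_cohort(scn)
    grid = scn.grid()
    binned = [_track_to_binned(t, grid) for t in tables]
    pooled = cohort_median(binned[:-1])
    ref_members = [gc_correct_safe(b, bias_source=pooled) for b in binned[:-1]]
    reference = cnum.build_reference(ref_members, grid)
    raw = binned[-1]
    corrected = gc_correct_safe(raw, bias_source=pooled)
    scaled = cnum.scale_library(corrected, reference)
    cn = cnum.estimate_cn(scaled, reference)
    return ScenarioResult(scn, grid, reference, cn, raw, corrected, truth, tables)


def cohort_median(samples: Sequence[BinnedCounts]) -> BinnedCounts | None:
    """Per-bin cross-sample median track, used as the GC-bias source so a
    test sample's own CNVs cannot distort its bias curve."""
    if not samples:
        return None
    mat = np.vstack([s.counts for s in samples])
    return BinnedCounts(samples[0].grid, np.median(mat, axis=0),
                        gc=samples[0].gc, sample_id="cohort_median")


def gc_correct_safe(b: BinnedCounts,
                    bias_source: BinnedCounts | None = None) -> BinnedCounts:
    """GC-correct when GC is available, otherwise pass through."""
    if b.gc is None or not np.isfinite(b.gc).any():
        return b
    return cnum.gc_correct(b, bias_source=bias_source)


def _track_to_binned(t: TrackTable, grid: BinGrid) -> BinnedCounts:
    """Counts track on exactly the grid's intervals -> BinnedCounts."""
    if len(t) == len(grid):
        same = all(
            iv.chrom == b.chrom and iv.start == b.start and iv.end == b.end
            for iv, b in zip(t.intervals(), grid.bins))
        if same:
            gc = t.df["gc"].to_numpy() if t.df["gc"].notna().any() else None
            return BinnedCounts(grid, t.df["N"].to_numpy(), gc=gc,
                                sample_id=t.sample_id, provenance=t.provenance)
    return aggregate_counts(t, grid)


def segment_median_cn(cn: cnum.CNEstimate, segment: GenomicInterval) -> float:
    """Median estimated CN over non-missing bins fully inside a segment."""
    vals = []
    for i, b in enumerate(cn.grid.bins):
        if (b.chrom == segment.chrom and b.start >= segment.start
                and b.end <= segment.end and not cn.flags["missing"][i]):
            vals.append(cn.cn[i])
    if not vals:
        # fall back to any overlap (focal events smaller than one bin)
        for i, b in enumerate(cn.grid.bins):
            if b.overlaps(segment) and not cn.flags["missing"][i]:
                vals.append(cn.cn[i])
    return float(np.median(vals)) if vals else float("nan")


def recovery_report(result: ScenarioResult) -> pd.DataFrame:
    """Per-truth-segment recovery: detected iff the segment-median CN moves
    from 2 in the true direction by at least half the true deviation."""
    rows = []
    for seg in result.scenario.cnv_segments:
        true_dev = seg.cn_eff - 2.0
        est = segment_median_cn(result.cn, seg.interval)
        est_dev = est - 2.0
        detected = (np.isfinite(est)
                    and est_dev * true_dev > 0
                    and abs(est_dev) >= 0.5 * abs(true_dev))
        rows.append({
            "chrom": seg.interval.chrom, "start": seg.interval.start,
            "end": seg.interval.end, "true_cn": seg.cn,
            "fraction": seg.fraction, "cn_eff": seg.cn_eff,
            "estimated_cn": est, "detected": bool(detected),
        })
    return pd.DataFrame(rows)
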