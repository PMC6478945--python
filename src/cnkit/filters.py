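"""Contextual filtering for clinical display: per-assay blacklists,
per-disease whitelists, canonical-transcript filtering and overflow flags.

Blacklisting flags bins instead of deleting them so masked values remain
inspectable (clinical audit trail).  Whitelists limit display annotations
only; CN tracks are never filtered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .copy_number import CNEstimate
from .genome import GenomeLayout, GenomicInterval, normalize_chrom
from .track_io import TrackTable


@dataclass
class RegionList:
    """A named blacklist or whitelist of intervals and/or gene labels."""

    name: str
    mode: str  # "blacklist" | "whitelist"
    regions: list  # GenomicInterval or str gene labels

    def __post_init__(self) -> None:
        if self.mode not in ("blacklist", "whitelist"):
            raise ValueError(f"mode must be blacklist or whitelist, got {self.mode!r}")
        if not self.regions:
            raise ValueError("region list must be non-empty")

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [r for r in self.regions if isinstance(r, GenomicInterval)]

    @property
    def gene_labels(self) -> set[str]:
        return {r for r in self.regions if isinstance(r, str)}

    @classmethod
    def from_bed(cls, path: str | Path, name: str, mode: str,
                 layout: GenomeLayout | None = None) -> "RegionList":
        regions = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            iv = GenomicInterval(normalize_chrom(f[0]), int(f[1]), int(f[2]))
            if layout is not None:
                layout.validate_interval(iv)
            regions.append(iv)
        return cls(name=name, mode=mode, regions=regions)

    @classmethod
    def from_gene_tsv(cls, path: str | Path, name: str,
                      mode: str = "whitelist") -> "RegionList":
        """Gene list: first column gene symbol; header optional."""
        genes = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sym = line.split("\t")[0]
            if sym.lower() in ("gene", "symbol"):
                continue
            genes.append(sym)
        return cls(name=name, mode=mode, regions=genes)


def apply_blacklist(cn: CNEstimate, bl: RegionList) -> CNEstimate:
    """Flag bins overlapping any blacklist region as masked; values kept."""
    if bl.mode != "blacklist":
        raise ValueError("apply_blacklist requires a blacklist RegionList")
    out = cn.copy()
    for i, b in enumerate(cn.grid.bins):
        for region in bl.intervals:
            if b.overlaps(region):
                out.flags["masked"][i] = True
                break
    return out


def apply_whitelist(annotation: TrackTable, wl: RegionList) -> TrackTable:
    """Keep only annotation records matching a whitelist gene or interval."""
    if wl.mode != "whitelist":
        raise ValueError("apply_whitelist requires a whitelist RegionList")
    genes = wl.gene_labels
    ivs = wl.intervals
    df = annotation.df

    def matches(row) -> bool:
        gene = row.gene if hasattr(row, "gene") and row.gene else row.label.split("|")[0]
        if gene in genes:
            return True
        here = GenomicInterval(row.chrom, int(row.start), int(row.end))
        return any(here.overlaps(iv) for iv in ivs)

    keep = [matches(r) for r in df.itertuples(index=False)]
    out = TrackTable(df[np.asarray(keep, dtype=bool)], kind=annotation.kind,
                     grid_label=annotation.grid_label,
                     sample_id=annotation.sample_id,
                     provenance=annotation.provenance + f";whitelist:{wl.name}")
    return out


def filter_transcripts(annotation: TrackTable,
                       canonical: Mapping[str, str]) -> TrackTable:
    """Retain one transcript per gene.

    Genes named in ``canonical`` keep that transcript; genes absent from the
    mapping keep their longest transcript (ties broken by lexicographically
    smallest transcript id).
    """
    df = annotation.df
    if "transcript" not in df.columns or "gene" not in df.columns:
        raise ValueError("annotation lacks gene/transcript columns")
    # transcript span length per (gene, transcript)
    spans = {}
    for row in df.itertuples(index=False):
        key = (row.gene, row.transcript)
        lo, hi = spans.get(key, (row.start, row.end))
        spans[key] = (min(lo, row.start), max(hi, row.end))
    chosen: dict[str, str] = {}
    for (gene, tx), (lo, hi) in sorted(spans.items()):
        if gene in canonical:
            continue
        length = hi - lo
        if gene not in chosen:
            chosen[gene] = tx
            continue
        cur = chosen[gene]
        cur_lo, cur_hi = spans[(gene, cur)]
        cur_len = cur_hi - cur_lo
        if length > cur_len or (length == cur_len and tx < cur):
            chosen[gene] = tx
    for gene, tx in canonical.items():
        chosen[gene] = tx
    keep = [chosen.get(r.gene) == r.transcript for r in df.itertuples(index=False)]
    return TrackTable(df[np.asarray(keep, dtype=bool)], kind=annotation.kind,
                      grid_label=annotation.grid_label,
                      sample_id=annotation.sample_id,
                      provenance=annotation.provenance + ";canonical")


def read_canonical_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV gene -> canonical transcript id."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if f[0].lower() in ("gene", "symbol"):
            continue
        out[f[0]] = f[1]
    return out


def flag_overflow(values: Sequence[float] | np.ndarray, ymax: float) -> np.ndarray:
    """True exactly where value > ymax (strict; ties display at the ceiling)."""
    if ymax <= 0:
        raise ValueError("ymax must be > 0")
    values = np.asarray(values, dtype=float)
    out = np.zeros(len(values), dtype=bool)
    finite = np.isfinite(values)
    out[finite] = values[finite] > ymax
    return out
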