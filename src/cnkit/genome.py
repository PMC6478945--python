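"""Genome coordinate system: chromosomes, cytobands, intervals and bin grids.

All coordinates are 0-based half-open internally (BED convention); 1-based
conventions are handled only at I/O boundaries that require them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Canonical ordering used when a layout is built from unordered input.
_CANONICAL_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y", "M", "MT"]

RESOLUTION_LABELS = ("genome", "arm", "region", "target")

#: Default bin sizes for the four display scales (target is bait-level, irregular).
DEFAULT_SCALES = {"genome": 1_000_000, "arm": 50_000, "region": 5_000}


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix to the canonical bare form."""
    name = name.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    return name


def denormalize_chrom(name: str, ucsc: bool = False) -> str:
    """Re-apply the ``chr`` prefix for UCSC-dialect output."""
    return f"chr{name}" if ucsc else name


def _is_primary_contig(name: str) -> bool:
    return name in _CANONICAL_ORDER


@dataclass(frozen=True)
class Chromosome:
    """A chromosome with its length and rank in genome-wide plots."""

    name: str
    length: int
    display_order: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be > 0")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_width(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Cytoband:
    interval: GenomicInterval
    band_name: str
    stain: str


class GenomeLayout:
    """Ordered chromosomes plus cytobands and the linear genome-wide axis.

    ``genome_offset`` maps each chromosome name to its cumulative bp offset
    so that any (chrom, pos) can be placed on a single genome-wide x-axis.
    """

    def __init__(
        self,
        chromosomes: Sequence[Chromosome],
        cytobands: Sequence[Cytoband] = (),
    ) -> None:
        if not chromosomes:
            raise ValueError("no chromosomes")
        chroms = sorted(chromosomes, key=lambda c: c.display_order)
        names = [c.name for c in chroms]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome names: {dupes}")
        self.chromosomes: list[Chromosome] = chroms
        self._by_name: dict[str, Chromosome] = {c.name: c for c in chroms}
        offsets: dict[str, int] = {}
        running = 0
        for c in chroms:
            offsets[c.name] = running
            running += c.length
        self.genome_offset: dict[str, int] = offsets
        self.total_length: int = running
        self.cytobands: list[Cytoband] = self._validate_cytobands(cytobands)

    def _validate_cytobands(self, cytobands: Sequence[Cytoband]) -> list[Cytoband]:
        kept = [b for b in cytobands if b.interval.chrom in self._by_name]
        kept.sort(key=lambda b: (self.chrom_rank(b.interval.chrom), b.interval.start))
        prev: Cytoband | None = None
        for b in kept:
            if prev is not None and prev.interval.chrom == b.interval.chrom:
                if b.interval.start < prev.interval.end:
                    raise ValueError(
                        f"overlapping cytobands {prev.band_name}/{b.band_name} "
                        f"on {b.interval.chrom}"
                    )
            prev = b
        return kept

    # -- lookups ---------------------------------------------------------

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._by_name

    def chromosome(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def chrom_rank(self, name: str) -> int:
        return self.chromosome(name).display_order

    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def validate_interval(self, iv: GenomicInterval) -> None:
        chrom = self.chromosome(iv.chrom)
        if iv.end > chrom.length:
            raise ValueError(
                f"interval {iv} extends beyond {iv.chrom} length {chrom.length}"
            )

    def locate(self, chrom: str, pos: int) -> int:
        """Map (chrom, pos) to the linear genome-wide coordinate."""
        c = self.chromosome(chrom)
        if not (0 <= pos <= c.length):
            raise ValueError(f"position {pos} outside {chrom} [0, {c.length}]")
        return self.genome_offset[chrom] + pos

    def sort_key(self, iv: GenomicInterval) -> tuple[int, int, int]:
        return (self.chrom_rank(iv.chrom), iv.start, iv.end)

    def cytobands_for(self, chrom: str) -> list[Cytoband]:
        return [b for b in self.cytobands if b.interval.chrom == chrom]

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_chrom_sizes(
        cls,
        path: str | Path,
        cytoband_path: str | Path | None = None,
        drop_nonprimary: bool = True,
    ) -> "GenomeLayout":
        """Build a layout from a two-column ``chrom.sizes`` TSV.

        Alt/patch contigs are dropped with a logged warning unless
        ``drop_nonprimary`` is False.
        """
        entries: list[tuple[str, int]] = []
        dropped = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            name, length = normalize_chrom(fields[0]), int(fields[1])
            if drop_nonprimary and not _is_primary_contig(name):
                dropped.append(name)
                continue
            entries.append((name, length))
        if dropped:
            logger.warning("dropped %d non-primary contigs: %s",
                           len(dropped), ", ".join(dropped[:5]))
        entries.sort(key=lambda e: _CANONICAL_ORDER.index(e[0])
                     if e[0] in _CANONICAL_ORDER else len(_CANONICAL_ORDER))
        chroms = [Chromosome(n, ln, i) for i, (n, ln) in enumerate(entries)]
        bands: list[Cytoband] = []
        if cytoband_path is not None:
            bands = read_cytobands(cytoband_path)
        return cls(chroms, bands)


def read_cytobands(path: str | Path) -> list[Cytoband]:
    """Parse a UCSC ``cytoBand.txt`` 5-column TSV."""
    bands = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(f"cytoband line {ln}: expected 5 columns, got {len(fields)}")
        chrom, start, end, band, stain = fields[:5]
        bands.append(
            Cytoband(GenomicInterval(normalize_chrom(chrom), int(start), int(end)),
                     band, stain)
        )
    return bands


@dataclass
class BinGrid:
    """Ordered, non-overlapping genomic intervals at one display resolution.

    ``bin_size`` is 0 for irregular (bait-level) grids.
    """

    resolution_label: str
    bin_size: int
    bins: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.bins, self.bins[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"overlapping bins {a} and {b}")

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinGrid):
            return NotImplemented
        return (self.resolution_label == other.resolution_label
                and self.bin_size == other.bin_size
                and self.bins == other.bins)

    def widths(self):
        import numpy as np

        return np.array([b.width for b in self.bins], dtype=float)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice of each chromosome's bins."""
        out: dict[str, slice] = {}
        start = 0
        for i, b in enumerate(self.bins):
            if b.chrom not in out:
                out[b.chrom] = slice(i, i + 1)
                start = i
            else:
                out[b.chrom] = slice(start, i + 1)
        return out


def tile_genome(layout: GenomeLayout, bin_size: int,
                resolution_label: str | None = None) -> BinGrid:
    """Tile every chromosome with fixed-width bins; terminal bins truncate.

    Every base of every chromosome is covered by exactly one bin.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if not layout.chromosomes:
        raise ValueError("no chromosomes")
    bins: list[GenomicInterval] = []
    for c in layout.chromosomes:
        n = math.ceil(c.length / bin_size)
        for i in range(n):
            bins.append(
                GenomicInterval(c.name, i * bin_size,
                                min((i + 1) * bin_size, c.length))
            )
    label = resolution_label or f"{bin_size}bp"
    return BinGrid(resolution_label=label, bin_size=bin_size, bins=bins)


def bait_grid(targets: Iterable[GenomicInterval],
              layout: GenomeLayout) -> BinGrid:
    """Build the irregular bait-level grid: validated, sorted, merged."""
    ivs = list(targets)
    for iv in ivs:
        try:
            layout.validate_interval(iv)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"bad target interval {iv}: {exc}") from exc
    ivs.sort(key=layout.sort_key)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return BinGrid(resolution_label="target", bin_size=0, bins=merged)


def build_scale_grids(
    layout: GenomeLayout,
    scales: Mapping[str, int] | None = None,
    bait_targets: Iterable[GenomicInterval] | None = None,
) -> dict[str, BinGrid]:
    """The four display grids: three fixed-size tilings plus the bait grid."""
    scales = dict(scales) if scales is not None else dict(DEFAULT_SCALES)
    grids = {label: tile_genome(layout, size, resolution_label=label)
             for label, size in scales.items()}
    if bait_targets is not None:
        grids["target"] = bait_grid(bait_targets, layout)
    return grids


#: hg19 primary-assembly chromosome lengths (bp).
HG19_SIZES: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}


def hg19_layout(divisor: int = 1) -> GenomeLayout:
    """hg19-like 24-chromosome layout, optionally scaled down by ``divisor``
    for fast simulation runs."""
    chroms = [Chromosome(name, max(1, length // divisor), i)
              for i, (name, length) in enumerate(HG19_SIZES.items())]
    return GenomeLayout(chroms)


def toy_layout(n_chrom: int = 3, length: int = 10_000_000) -> GenomeLayout:
    """Small layout for tests and fast CI runs."""
    chroms = [Chromosome(str(i + 1), length, i) for i in range(n_chrom)]
    bands = []
    for c in chroms:
        mid = c.length // 2
        bands.append(Cytoband(GenomicInterval(c.name, 0, mid), "p11", "gneg"))
        bands.append(Cytoband(GenomicInterval(c.name, mid, c.length), "q11", "gpos50"))
    return GenomeLayout(chroms, bands)
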