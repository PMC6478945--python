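"""Readers and writers for the index table and all track tables.

Every table is tab-separated text with a header line.  The track dialect is a
minimal superset: mandatory columns ``chrom``, ``start``, ``end``, ``N`` plus
optional ``sd``, ``gc``, ``label``.  Coordinates in files are 0-based
half-open.  Writers emit LF line endings and 6-significant-digit floats so
output is byte-deterministic; readers accept LF and CRLF.
"""

from __future__ import annotations

import io
import logging
import math
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import GenomeLayout, GenomicInterval, normalize_chrom

logger = logging.getLogger(__name__)

TRACK_KINDS = (
    "counts", "cn_bins", "cn_segments", "breakpoints", "baf",
    "annotation", "cytoband", "chromosomes",
)

_CORE_COLUMNS = ["chrom", "start", "end", "N", "sd", "gc", "label"]

#: Maximum bytes fetched from a URL source.
URL_SIZE_CAP = 500 * 1024 * 1024


@dataclass(frozen=True)
class TrackRecord:
    """One per-interval record: the value column ``N`` plus optional extras."""

    interval: GenomicInterval
    N: float
    sd: float | None = None
    gc: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.sd is not None and not math.isnan(self.sd) and self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.gc is not None and not math.isnan(self.gc) and not 0 <= self.gc <= 1:
            raise ValueError("gc must be in [0, 1]")


@dataclass(frozen=True)
class BreakpointRecord:
    """A paired-end structural-variant breakpoint with read support."""

    end1: GenomicInterval
    end2: GenomicInterval
    support: int
    type: str = ""

    def __post_init__(self) -> None:
        if self.support < 0:
            raise ValueError("support must be >= 0")


class TrackTable:
    """Ordered per-interval records of one kind, backed by a DataFrame.

    The frame always carries the core columns ``chrom``, ``start``, ``end``,
    ``N``, ``sd``, ``gc``, ``label``; extra kind-specific columns are kept.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        kind: str,
        grid_label: str = "irregular",
        sample_id: str = "",
        provenance: str = "",
        layout: GenomeLayout | None = None,
    ) -> None:
        if kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {kind!r}; one of {TRACK_KINDS}")
        df = df.copy()
        for col in _CORE_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col == "label" else np.nan
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        for col in ("N", "sd", "gc"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        df["label"] = df["label"].fillna("").astype(str)
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"record {bad}: start >= end")
        sd = df["sd"].to_numpy()
        if np.any(sd[~np.isnan(sd)] < 0):
            raise ValueError("sd must be >= 0")
        gc = df["gc"].to_numpy()
        ok = ~np.isnan(gc)
        if np.any((gc[ok] < 0) | (gc[ok] > 1)):
            raise ValueError("gc must be in [0, 1]")
        if kind == "baf":
            n = df["N"].to_numpy()
            good = ~np.isnan(n)
            if np.any((n[good] < 0) | (n[good] > 1)):
                raise ValueError("baf values must be in [0, 1]")
        df = _sort_genomic(df, layout)
        extra = [c for c in df.columns if c not in _CORE_COLUMNS]
        self.df = df[_CORE_COLUMNS + sorted(extra)].reset_index(drop=True)
        self.kind = kind
        self.grid_label = grid_label
        self.sample_id = sample_id
        self.provenance = provenance
        self.n_dropped = 0  # rows dropped at read time (unknown contigs)

    # ------------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[TrackRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(TrackRecord(
                GenomicInterval(row.chrom, int(row.start), int(row.end)),
                float(row.N),
                sd=None if pd.isna(row.sd) else float(row.sd),
                gc=None if pd.isna(row.gc) else float(row.gc),
                label=row.label or None,
            ))
        return out

    def intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(c, int(s), int(e))
                for c, s, e in zip(self.df["chrom"], self.df["start"], self.df["end"])]

    def copy(self) -> "TrackTable":
        t = TrackTable(self.df, self.kind, self.grid_label,
                       self.sample_id, self.provenance)
        t.n_dropped = self.n_dropped
        return t

    @classmethod
    def from_arrays(cls, intervals: Iterable[GenomicInterval], N,
                    kind: str, sd=None, gc=None, labels=None,
                    **meta) -> "TrackTable":
        ivs = list(intervals)
        df = pd.DataFrame({
            "chrom": [iv.chrom for iv in ivs],
            "start": [iv.start for iv in ivs],
            "end": [iv.end for iv in ivs],
            "N": np.asarray(list(N), dtype=float),
        })
        if sd is not None:
            df["sd"] = np.asarray(list(sd), dtype=float)
        if gc is not None:
            df["gc"] = np.asarray(list(gc), dtype=float)
        if labels is not None:
            df["label"] = list(labels)
        return cls(df, kind=kind, **meta)


def _chrom_rank_series(chroms: pd.Series, layout: GenomeLayout | None) -> pd.Series:
    if layout is not None:
        return chroms.map(lambda c: layout.chrom_rank(c))

    def natural(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    return chroms.map(natural)


def _sort_genomic(df: pd.DataFrame, layout: GenomeLayout | None) -> pd.DataFrame:
    tmp = df.assign(_rank=_chrom_rank_series(df["chrom"], layout))
    tmp = tmp.sort_values(["_rank", "start", "end"], kind="mergesort")
    return tmp.drop(columns="_rank")


# ----------------------------------------------------------------------
# locators


def _read_text(locator: str | Path) -> str:
    """Read text from a path or http(s) URL (size-capped)."""
    loc = str(locator)
    if loc.startswith(("http://", "https://")):
        with urllib.request.urlopen(loc) as resp:  # noqa: S310 - explicit opt-in
            data = resp.read(URL_SIZE_CAP + 1)
        if len(data) > URL_SIZE_CAP:
            raise ValueError(f"remote resource exceeds size cap: {loc}")
        return data.decode()
    return Path(locator).read_text()


def _format_float(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


# ----------------------------------------------------------------------
# track read/write


def read_track(path: str | Path, kind: str,
               layout: GenomeLayout | None = None, **meta) -> TrackTable:
    """Read one track table, validating records against the layout.

    Rows on chromosomes absent from the layout are dropped; the count of
    dropped rows is recorded on the returned table and logged.
    """
    text = _read_text(path)
    if not text.strip():
        raise ValueError(f"empty track file: {path}")
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype={"chrom": str, "label": str})
    missing = [c for c in ("chrom", "start", "end", "N") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    bad_n = pd.to_numeric(df["N"], errors="coerce").isna() & df["N"].notna()
    if bad_n.any():
        line = int(df.index[bad_n][0]) + 2  # header is line 1
        raise ValueError(f"{path}: non-numeric N at line {line}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    n_dropped = 0
    if layout is not None:
        keep = df["chrom"].map(lambda c: c in layout)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("%s: dropped %d rows on unknown chromosomes",
                           path, n_dropped)
        df = df[keep]
        for row in df.itertuples(index=False):
            if int(row.end) > layout.chromosome(row.chrom).length:
                raise ValueError(
                    f"{path}: interval {row.chrom}:{row.start}-{row.end} "
                    "beyond chromosome end")
    table = TrackTable(df, kind=kind, layout=layout, **meta)
    table.n_dropped = n_dropped
    return table


def write_track(table: TrackTable, path: str | Path) -> None:
    """Write a canonical TSV: fixed column order, sorted rows, LF, %.6g floats."""
    df = table.df
    extra = [c for c in df.columns if c not in _CORE_COLUMNS]
    cols = _CORE_COLUMNS + extra
    lines = ["\t".join(cols)]
    for row in df.itertuples(index=False):
        d = row._asdict()
        fields = [
            str(d["chrom"]), str(int(d["start"])), str(int(d["end"])),
            _format_float(d["N"]), _format_float(d["sd"]), _format_float(d["gc"]),
            str(d["label"]),
        ]
        for c in extra:
            v = d[c]
            fields.append(_format_float(v) if isinstance(v, float) else str(v))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# index table

INDEX_COLUMNS = ["sample_id", "kind", "resolution", "path", "name"]


class IndexTable:
    """Catalogue of all displayable tables for one or more samples.

    Mandatory columns: sample_id, kind, resolution, path, name; an optional
    ``group`` column supports non-interactive reference-set selection.
    Unknown extra columns are preserved as metadata.
    """

    def __init__(self, df: pd.DataFrame, base_dir: Path | None = None) -> None:
        missing = [c for c in INDEX_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"index: missing mandatory column(s): {', '.join(missing)}")
        df = df.copy()
        if "group" not in df.columns:
            df["group"] = ""
        df["group"] = df["group"].fillna("").astype(str)
        key = df[["sample_id", "kind", "resolution"]].astype(str)
        dup = key.duplicated(keep=False)
        if dup.any():
            collisions = key[dup].drop_duplicates().to_records(index=False).tolist()
            raise ValueError(f"index: duplicate (sample_id, kind, resolution) keys: "
                             f"{collisions}")
        self.df = df.reset_index(drop=True)
        self.base_dir = base_dir

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.df["sample_id"]:
            if s not in seen:
                seen.append(s)
        return seen

    @property
    def multi_sample(self) -> bool:
        """Multi-sample mode turns on when more than one sample is indexed."""
        return len(self.sample_ids) > 1

    def resolve_path(self, path: str) -> str:
        if str(path).startswith(("http://", "https://")):
            return str(path)
        p = Path(path)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return str(p)

    def lookup(self, sample_id: str, kind: str,
               resolution: str | None = None) -> pd.DataFrame:
        m = (self.df["sample_id"] == sample_id) & (self.df["kind"] == kind)
        if resolution is not None:
            m &= self.df["resolution"] == resolution
        return self.df[m]

    def group_members(self, group: str) -> list[str]:
        out: list[str] = []
        for s, g in zip(self.df["sample_id"], self.df["group"]):
            if g == group and s not in out:
                out.append(s)
        return out

    def write(self, path: str | Path) -> None:
        cols = INDEX_COLUMNS + ["group"] + [
            c for c in self.df.columns if c not in INDEX_COLUMNS + ["group"]]
        lines = ["\t".join(cols)]
        for row in self.df[cols].itertuples(index=False):
            lines.append("\t".join(str(v) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def read_index(path_or_url: str | Path, check_paths: bool = False) -> IndexTable:
    """Load and validate the index table from a file path or URL."""
    text = _read_text(path_or_url)
    if not text.strip():
        raise ValueError(f"empty index file: {path_or_url}")
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str).fillna("")
    base = None
    if not str(path_or_url).startswith(("http://", "https://")):
        base = Path(path_or_url).resolve().parent
    idx = IndexTable(df, base_dir=base)
    if check_paths:
        for p in idx.df["path"]:
            rp = idx.resolve_path(p)
            if not rp.startswith(("http://", "https://")) and not Path(rp).exists():
                logger.warning("index references missing path: %s", rp)
    return idx


# ----------------------------------------------------------------------
# caller-output ingestion

CALLER_DIALECTS = ("seg", "bedgraph", "ratio_table")


def import_caller_output(path: str | Path, dialect: str,
                         layout: GenomeLayout | None = None,
                         sample_id: str = "") -> TrackTable:
    """Convert third-party caller output into a displayable CN track.

    ``seg``: SEG format (1-based inclusive, ``seg.mean`` is a log2 ratio);
    converted to linear CN via CN = 2 * 2**log2ratio.
    ``bedgraph``: 4-column BED-like, value taken as linear CN.
    ``ratio_table``: chrom/start/end/ratio with a linear ratio (CN = 2*ratio).
    """
    if dialect not in CALLER_DIALECTS:
        raise ValueError(
            f"unrecognized dialect {dialect!r}; supported: {', '.join(CALLER_DIALECTS)}")
    text = _read_text(path)
    if dialect == "seg":
        df = pd.read_csv(io.StringIO(text), sep="\t")
        cols = {c.lower(): c for c in df.columns}
        chrom_c = cols.get("chrom") or cols.get("chromosome")
        start_c = cols.get("loc.start") or cols.get("start")
        end_c = cols.get("loc.end") or cols.get("end")
        mean_c = cols.get("seg.mean") or cols.get("seg_mean")
        if not all([chrom_c, start_c, end_c, mean_c]):
            raise ValueError(f"{path}: not a SEG file (need chrom/loc.start/loc.end/seg.mean)")
        out = pd.DataFrame({
            "chrom": df[chrom_c].astype(str).map(normalize_chrom),
            "start": df[start_c].astype(np.int64) - 1,  # 1-based inclusive -> 0-based
            "end": df[end_c].astype(np.int64),
            "N": 2.0 * np.power(2.0, df[mean_c].astype(float)),
        })
        kind = "cn_segments"
    elif dialect == "bedgraph":
        df = pd.read_csv(io.StringIO(text), sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "N"],
                         dtype={0: str})
        out = df.assign(chrom=df["chrom"].map(normalize_chrom))
        kind = "cn_bins"
    else:  # ratio_table
        df = pd.read_csv(io.StringIO(text), sep="\t")
        need = [c for c in ("chrom", "start", "end", "ratio") if c not in df.columns]
        if need:
            raise ValueError(f"{path}: ratio_table missing columns: {need}")
        out = pd.DataFrame({
            "chrom": df["chrom"].astype(str).map(normalize_chrom),
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "N": 2.0 * df["ratio"].astype(float),
        })
        kind = "cn_bins"
    if layout is not None:
        keep = out["chrom"].map(lambda c: c in layout)
        out = out[keep]
    return TrackTable(out, kind=kind, layout=layout, sample_id=sample_id,
                      provenance=f"imported:{dialect}")


# ----------------------------------------------------------------------
# annotations


def read_annotation(path: str | Path, dialect: str,
                    layout: GenomeLayout | None = None) -> TrackTable:
    """Read transcript annotations to exon-level records.

    One record per exon labelled ``GENE|transcript|exonN``; exon numbering
    follows transcription order (exon 1 is the 3'-most genomic exon for a
    minus-strand transcript).  The N column carries the exon number.
    """
    if dialect == "refflat":
        rows = _parse_refflat(_read_text(path), path)
    elif dialect == "gtf":
        rows = _parse_gtf_exons(_read_text(path), path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}; use refflat or gtf")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "N", "label",
                                     "gene", "transcript", "strand"])
    if layout is not None:
        df = df[df["chrom"].map(lambda c: c in layout)]
    return TrackTable(df, kind="annotation", layout=layout,
                      provenance=f"annotation:{dialect}")


def _parse_refflat(text: str, path) -> list[tuple]:
    rows = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 11:
            raise ValueError(f"{path}: malformed refFlat row at line {ln}")
        gene, tx, chrom, strand = f[0], f[1], normalize_chrom(f[2]), f[3]
        try:
            exon_count = int(f[8])
            starts = [int(x) for x in f[9].rstrip(",").split(",")]
            ends = [int(x) for x in f[10].rstrip(",").split(",")]
        except ValueError as exc:
            raise ValueError(f"{path}: malformed refFlat row at line {ln}: {exc}")
        if len(starts) != exon_count or len(ends) != exon_count:
            raise ValueError(f"{path}: exon list length mismatch at line {ln}")
        for i, (s, e) in enumerate(zip(starts, ends)):
            num = i + 1 if strand != "-" else exon_count - i
            rows.append((chrom, s, e, float(num),
                         f"{gene}|{tx}|exon{num}", gene, tx, strand))
    return rows


def _parse_gtf_exons(text: str, path) -> list[tuple]:
    import re

    exons: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise ValueError(f"{path}: malformed GTF row at line {ln}")
        if f[2] != "exon":
            continue
        chrom, start, end, strand, attrs = (
            normalize_chrom(f[0]), int(f[3]) - 1, int(f[4]), f[6], f[8])

        def attr(key: str) -> str | None:
            m = re.search(rf'{key} "([^"]+)"', attrs)
            return m.group(1) if m else None

        tx = attr("transcript_id")
        gene = attr("gene_name") or attr("gene_id") or ""
        if tx is None:
            raise ValueError(f"{path}: exon without transcript_id at line {ln}")
        exons.setdefault(tx, []).append((start, end))
        meta[tx] = (gene, chrom, strand)
    rows = []
    for tx, ivs in exons.items():
        gene, chrom, strand = meta[tx]
        ivs.sort()
        n = len(ivs)
        for i, (s, e) in enumerate(ivs):
            num = i + 1 if strand != "-" else n - i
            rows.append((chrom, s, e, float(num),
                         f"{gene}|{tx}|exon{num}", gene, tx, strand))
    return rows


# ----------------------------------------------------------------------
# breakpoints


def read_breakpoints(path: str | Path,
                     layout: GenomeLayout | None = None) -> list[BreakpointRecord]:
    """Read a BEDPE-like 8-column breakpoint table:
    chrom1 start1 end1 chrom2 start2 end2 type support."""
    text = _read_text(path)
    records = []
    lines = text.splitlines()
    start_at = 1 if lines and lines[0].startswith(("chrom1", "#")) else 0
    for ln, line in enumerate(lines[start_at:], start_at + 1):
        line = line.strip()
        if not line:
            continue
        f = line.split("\t")
        if len(f) < 8:
            raise ValueError(f"{path}: expected 8 columns at line {ln}")
        end1 = GenomicInterval(normalize_chrom(f[0]), int(f[1]), int(f[2]))
        end2 = GenomicInterval(normalize_chrom(f[3]), int(f[4]), int(f[5]))
        if layout is not None and (end1.chrom not in layout or end2.chrom not in layout):
            continue
        records.append(BreakpointRecord(end1, end2, support=int(f[7]), type=f[6]))
    return records


def write_breakpoints(records: Iterable[BreakpointRecord], path: str | Path) -> None:
    lines = ["\t".join(["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                        "type", "support"])]
    for r in records:
        lines.append("\t".join([
            r.end1.chrom, str(r.end1.start), str(r.end1.end),
            r.end2.chrom, str(r.end2.start), str(r.end2.end),
            r.type, str(r.support)]))
    Path(path).write_text("\n".join(lines) + "\n")
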