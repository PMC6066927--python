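"""Genomic data model, standard-format I/O, binning, masking and depth normalization.

All coordinates are 0-based half-open (BED convention). GTF input, which is
1-based closed, is converted on ingestion. Coverage is held as fixed-width
binned tracks, one per chromosome per strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Gene",
    "BinnedTrack",
    "FeatureSet",
    "ParseError",
    "ValidationError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_intervals",
    "read_genes",
    "write_bed",
    "write_genes_bed12",
    "read_bedgraph",
    "write_bedgraph",
    "exclude_regions",
    "normalize_depth",
    "normalize_sample_tracks",
]

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Raised when a file cannot be parsed in the declared dialect."""


class ValidationError(ValueError):
    """Raised when data violates a documented invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A located, optionally stranded genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class Gene:
    """A gene with orientation-aware anchors and a scalar expression level.

    ``tss`` is the start coordinate for + genes and the end coordinate for
    - genes; ``pas`` is the opposite end.
    """

    id: str
    interval: GenomicInterval
    expression: float = 0.0

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def pas(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class BinnedTrack:
    """Fixed-width per-strand coverage for one chromosome.

    ``values`` holds one non-negative number per bin; bin i covers
    [i*bin_width, min((i+1)*bin_width, chrom_length)). ``mask`` marks bins
    excluded from all downstream counting, fitting and matching.
    """

    chrom: str
    bin_width: int
    strand: str
    values: np.ndarray
    chrom_length: int
    mapped_read_total: float = 0.0
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = math.ceil(self.chrom_length / self.bin_width)
        if len(self.values) != expected:
            raise ValidationError(
                f"{self.chrom}: expected {expected} bins, got {len(self.values)}"
            )
        if np.any(self.values < 0):
            raise ValidationError("track values must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(len(self.values), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def bin_range(self, start: int, end: int) -> tuple[int, int]:
        """Indices of bins overlapping [start, end)."""
        lo = max(0, start // self.bin_width)
        hi = min(self.n_bins, -(-end // self.bin_width))
        return lo, hi

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            chrom=self.chrom,
            bin_width=self.bin_width,
            strand=self.strand,
            values=self.values.copy(),
            chrom_length=self.chrom_length,
            mapped_read_total=self.mapped_read_total,
            mask=self.mask.copy(),
        )


@dataclass
class FeatureSet:
    """A named collection of intervals (LADs, histone-mark patches, origins...)."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def sorted(self) -> "FeatureSet":
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return FeatureSet(self.name, ivs)

    def merged(self) -> "FeatureSet":
        """Per-chromosome union of intervals (strand discarded)."""
        out: list[GenomicInterval] = []
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom], key=lambda iv: iv.start)
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_e:
                    cur_e = max(cur_e, iv.end)
                else:
                    out.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            out.append(GenomicInterval(chrom, cur_s, cur_e))
        return FeatureSet(self.name, out)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Merged intervals as {chrom: (n,2) array of [start, end)} for fast lookup."""
        merged = self.merged()
        out: dict[str, list[list[int]]] = {}
        for iv in merged.intervals:
            out.setdefault(iv.chrom, []).append([iv.start, iv.end])
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


# ---------------------------------------------------------------------------
# chrom.sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{ln}: expected two tab-separated columns")
        try:
            sizes[parts[0]] = int(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: bad chromosome length") from exc
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# BED / GTF intervals
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, ln: int, path) -> tuple[list[str], int, int]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        raise ParseError(f"{path}:{ln}: BED line has fewer than 3 columns")
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
    if end <= start:
        raise ValidationError(f"{path}:{ln}: end <= start")
    return parts, start, end


def read_intervals(path, format: str = "BED6", name: str | None = None) -> FeatureSet:
    """Read a BED3/BED6 file into a FeatureSet.

    Use :func:`read_genes` for BED12/GTF gene models.
    """
    if format not in ("BED3", "BED6"):
        raise ValueError(f"unsupported interval format {format!r}")
    ivs: list[GenomicInterval] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts, start, end = _parse_bed_line(line, ln, path)
        strand = "."
        if format == "BED6" and len(parts) >= 6 and parts[5] in STRANDS:
            strand = parts[5]
        ivs.append(GenomicInterval(parts[0], start, end, strand))
    return FeatureSet(name or Path(path).stem, ivs)


def read_genes(path, format: str = "BED12", expression: dict[str, float] | None = None) -> list[Gene]:
    """Read gene models from BED12 or GTF.

    GTF rows with feature type ``gene`` are used; 1-based closed coordinates
    are converted to 0-based half-open. ``expression`` optionally attaches a
    per-gene abundance by gene id.
    """
    expression = expression or {}
    genes: list[Gene] = []
    if format == "BED12":
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts, start, end = _parse_bed_line(line, ln, path)
            if len(parts) < 6:
                raise ParseError(f"{path}:{ln}: BED12 requires >= 6 columns")
            gid = parts[3]
            strand = parts[5] if parts[5] in STRANDS else "."
            genes.append(
                Gene(gid, GenomicInterval(parts[0], start, end, strand),
                     expression.get(gid, 0.0))
            )
    elif format == "GTF":
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{ln}: GTF requires 9 columns")
            if parts[2] != "gene":
                continue
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            if end1 < start1:
                raise ValidationError(f"{path}:{ln}: end < start")
            gid = f"line{ln}"
            for item in parts[8].split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gid = item.split(None, 1)[1].strip().strip('"')
                    break
            strand = parts[6] if parts[6] in STRANDS else "."
            genes.append(
                Gene(gid, GenomicInterval(parts[0], start1 - 1, end1, strand),
                     expression.get(gid, 0.0))
            )
    else:
        raise ValueError(f"unsupported gene format {format!r}")
    return genes


def write_bed(intervals: Iterable[GenomicInterval], path, names=None, scores=None) -> None:
    intervals = list(intervals)
    names = list(names) if names is not None else ["."] * len(intervals)
    scores = list(scores) if scores is not None else [0] * len(intervals)
    with open(path, "w") as fh:
        for iv, nm, sc in zip(intervals, names, scores):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{nm}\t{sc}\t{iv.strand}\n")


def write_genes_bed12(genes: Sequence[Gene], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.id}\t0\t{iv.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t1\t{iv.length},\t0,\n"
            )


# ---------------------------------------------------------------------------
# bedGraph <-> BinnedTrack
# ---------------------------------------------------------------------------

def read_bedgraph(path, chrom_sizes: dict[str, int], bin_width: int,
                  strand: str = ".") -> dict[str, BinnedTrack]:
    """Bin a bedGraph into one track per chromosome.

    Each bin value is the length-weighted mean of the covering bedGraph values
    over the bin's span; uncovered bases contribute 0. Every chromosome in
    ``chrom_sizes`` yields a track (all-zero if absent from the file).
    """
    acc = {
        c: np.zeros(math.ceil(n / bin_width)) for c, n in chrom_sizes.items()
    }
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise ParseError(f"{path}:{ln}: bedGraph requires 4 columns")
        chrom = parts[0]
        try:
            start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: bad coordinates or value") from exc
        if end <= start:
            raise ValidationError(f"{path}:{ln}: end <= start")
        if chrom not in chrom_sizes:
            raise ValidationError(f"{path}:{ln}: unknown chromosome {chrom!r}")
        if end > chrom_sizes[chrom]:
            raise ValidationError(f"{path}:{ln}: interval past chromosome end")
        a = acc[chrom]
        b0, b1 = start // bin_width, (end - 1) // bin_width
        if b0 == b1:
            a[b0] += value * (end - start)
        else:
            a[b0] += value * ((b0 + 1) * bin_width - start)
            if b1 > b0 + 1:
                a[b0 + 1:b1] += value * bin_width
            a[b1] += value * (end - b1 * bin_width)
    out = {}
    for chrom, a in acc.items():
        length = chrom_sizes[chrom]
        widths = np.full(len(a), float(bin_width))
        if length % bin_width:
            widths[-1] = length % bin_width
        out[chrom] = BinnedTrack(
            chrom=chrom, bin_width=bin_width, strand=strand,
            values=a / widths, chrom_length=length,
        )
    return out


def write_bedgraph(tracks: dict[str, BinnedTrack] | Sequence[BinnedTrack], path) -> None:
    """Write binned tracks as a bedGraph, one line per non-zero bin run."""
    if isinstance(tracks, dict):
        tracks = [tracks[c] for c in sorted(tracks)]
    with open(path, "w") as fh:
        for tr in tracks:
            vals = tr.values
            if not len(vals):
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [tr.n_bins]])
            for i, j in zip(starts, ends):
                v = vals[i]
                if v != 0.0:
                    start = int(i) * tr.bin_width
                    end = min(int(j) * tr.bin_width, tr.chrom_length)
                    fh.write(f"{tr.chrom}\t{start}\t{end}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Blacklist exclusion and depth normalization
# ---------------------------------------------------------------------------

def exclude_regions(data, blacklist: FeatureSet):
    """Mask bins / drop intervals overlapping the blacklist (any-overlap).

    Accepts a BinnedTrack, a dict of tracks, a FeatureSet or a list of
    intervals; returns the same type. Idempotent; an empty blacklist is the
    identity.
    """
    bl = blacklist.by_chrom()

    def _mask_track(tr: BinnedTrack) -> BinnedTrack:
        out = tr.copy()
        for start, end in bl.get(tr.chrom, np.empty((0, 2), dtype=np.int64)):
            lo, hi = out.bin_range(int(start), int(end))
            out.mask[lo:hi] = True
        return out

    def _hits(iv: GenomicInterval) -> bool:
        arr = bl.get(iv.chrom)
        if arr is None or not len(arr):
            return False
        idx = np.searchsorted(arr[:, 0], iv.end)
        return bool(idx > 0 and arr[idx - 1, 1] > iv.start) or bool(
            idx < len(arr) and arr[idx, 0] < iv.end
        )

    if isinstance(data, BinnedTrack):
        return _mask_track(data)
    if isinstance(data, dict):
        return {k: _mask_track(v) for k, v in data.items()}
    if isinstance(data, FeatureSet):
        return FeatureSet(data.name, [iv for iv in data.intervals if not _hits(iv)])
    if isinstance(data, list):
        return [iv for iv in data if not _hits(iv)]
    raise TypeError(f"unsupported input type {type(data)!r}")


def normalize_depth(tracks: Sequence[BinnedTrack],
                    totals: Sequence[float] | None = None) -> list[BinnedTrack]:
    """Scale each track by reference_total / mapped_read_total.

    The reference is the geometric mean of the distinct per-track totals, so
    the output is invariant under relabeling of samples. Ratios between bins
    within a track are preserved exactly.
    """
    if totals is None:
        totals = [tr.mapped_read_total for tr in tracks]
    totals = np.asarray(totals, dtype=float)
    if np.any(totals <= 0):
        raise ValidationError("mapped_read_total must be > 0 for every track")
    reference = float(np.exp(np.mean(np.log(totals))))
    out = []
    for tr, total in zip(tracks, totals):
        scaled = tr.copy()
        scaled.values = tr.values * (reference / total)
        out.append(scaled)
    return out


def normalize_sample_tracks(samples: dict[str, dict], totals: dict[str, float]) -> dict[str, dict]:
    """Depth-normalize {sample: {key: BinnedTrack}} using one total per sample."""
    names = sorted(samples)
    tvec = np.asarray([totals[s] for s in names], dtype=float)
    if np.any(tvec <= 0):
        raise ValidationError("mapped_read_total must be > 0 for every sample")
    reference = float(np.exp(np.mean(np.log(tvec))))
    out: dict[str, dict] = {}
    for s, total in zip(names, tvec):
        scale = reference / total
        out[s] = {}
        for key, tr in samples[s].items():
            sc = tr.copy()
            sc.values = tr.values * scale
            out[s][key] = sc
    return out
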