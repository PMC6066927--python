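"""Strand-aware metagene and anchor-centered profiles.

Positions are reported in transcription orientation: profiles of minus-strand
genes are mirrored before aggregation, so upstream is always to the left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import BinnedTrack, FeatureSet, Gene, ValidationError

__all__ = [
    "MetaProfile",
    "PausingCall",
    "metagene_peak_density",
    "signal_metaplot",
    "lad_boundary_promoter_density",
    "pausing_index",
    "tss_ratio_profile",
]


@dataclass
class MetaProfile:
    """A per-position summary (median/mean/density) with its spread."""

    anchor: str
    positions: np.ndarray
    summary: np.ndarray
    spread: np.ndarray
    group: str = ""
    n: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.summary = np.asarray(self.summary, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if len(self.summary) != len(self.positions):
            raise ValidationError("summary length must match positions")


@dataclass(frozen=True)
class PausingCall:
    gene_id: str
    index: float
    category: str  # paused | non-paused | low-expressed


def metagene_peak_density(peaks, genes: list[Gene],
                          length_categories: dict[str, tuple[float, float]] | None = None,
                          n_bins: int = 40) -> dict[str, MetaProfile]:
    """Scaled-gene peak-count metagene, normalized per gene in each category.

    Each gene span is divided into ``n_bins`` equal bins (mirrored for minus
    genes); a peak adds 1 to every bin it overlaps; bin counts are divided by
    the number of genes in the length category. Empty categories are omitted.
    """
    if length_categories is None:
        length_categories = {"all": (0, float("inf"))}
    by_chrom: dict[str, list] = {}
    for p in peaks:
        iv = p.interval if hasattr(p, "interval") else p
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: dict[str, MetaProfile] = {}
    for cat, (lo, hi) in length_categories.items():
        members = [g for g in genes if lo <= g.length < hi]
        if not members:
            continue
        counts = np.zeros(n_bins)
        for g in members:
            binw = g.length / n_bins
            for iv in by_chrom.get(g.chrom, []):
                if iv.strand != "." and g.strand != "." and iv.strand != g.strand:
                    continue
                ov0 = max(iv.start, g.start)
                ov1 = min(iv.end, g.end)
                if ov1 <= ov0:
                    continue
                b0 = int((ov0 - g.start) / binw)
                b1 = min(n_bins - 1, int((ov1 - 1 - g.start) / binw))
                if g.strand == "-":
                    b0, b1 = n_bins - 1 - b1, n_bins - 1 - b0
                counts[b0:b1 + 1] += 1.0
        out[cat] = MetaProfile(
            anchor="scaled-gene-40bin",
            positions=(np.arange(n_bins) + 0.5) / n_bins,
            summary=counts / len(members),
            spread=np.zeros(n_bins),
            group=cat,
            n=len(members),
        )
    return out


def _extract_window(track: BinnedTrack, center: int, half_bins: int) -> np.ndarray | None:
    """Values over [center - W, center + W) in bins, or None if off-chromosome."""
    c = center // track.bin_width
    lo, hi = c - half_bins, c + half_bins
    if lo < 0 or hi > track.n_bins:
        return None
    return track.values[lo:hi]


def signal_metaplot(tracks: dict[tuple[str, str], BinnedTrack],
                    genes: list[Gene], anchor: str = "TSS",
                    window: int = 20000, strand_mode: str = "template",
                    summary: str = "median", spread: str = "sd",
                    group: str = "") -> MetaProfile:
    """Anchor-centered strand-resolved signal metaplot.

    ``tracks`` maps (chrom, strand) to a depth-normalized track. The template
    strand is the track strand equal to the gene's annotated strand. Windows
    are mirrored for minus genes; genes whose window leaves the chromosome
    are skipped (the count is recorded on the returned profile's ``n``).
    """
    if anchor not in ("TSS", "PAS"):
        raise ValueError("anchor must be TSS or PAS")
    if strand_mode not in ("template", "non_template", "unstranded"):
        raise ValueError(f"bad strand_mode {strand_mode!r}")
    some = next(iter(tracks.values()))
    bw = some.bin_width
    half_bins = window // (2 * bw)
    rows = []
    for g in genes:
        if strand_mode == "unstranded":
            strand = "."
        elif strand_mode == "template":
            strand = g.strand
        else:
            strand = "-" if g.strand == "+" else "+"
        tr = tracks.get((g.chrom, strand))
        if tr is None:
            continue
        center = g.tss if anchor == "TSS" else g.pas
        win = _extract_window(tr, center, half_bins)
        if win is None:
            continue
        rows.append(win[::-1] if g.strand == "-" else win)
    if not rows:
        raise ValidationError("no gene window fits on the chromosomes")
    mat = np.vstack(rows)
    positions = (np.arange(-half_bins, half_bins) + 0.5) * bw
    summ = np.median(mat, axis=0) if summary == "median" else mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    sp = sd if spread == "sd" else sd / np.sqrt(len(rows))
    return MetaProfile(anchor=f"{anchor}+/-{window // 2}", positions=positions,
                       summary=summ, spread=sp, group=group, n=len(rows))


def lad_boundary_promoter_density(genes: list[Gene], lads: FeatureSet,
                                  window: int = 200_000, bin_width: int = 10_000,
                                  orientation: str = "away",
                                  group: str = "") -> MetaProfile:
    """TSS density around LAD boundaries, split by transcription orientation.

    Positions are signed so negative means inside the LAD. A gene is counted
    at its nearest boundary only. ``away`` keeps genes transcribing out of
    the LAD interior, ``toward`` those transcribing into it. Density is TSS
    count per bin per boundary.
    """
    if orientation not in ("away", "toward"):
        raise ValueError(f"bad orientation {orientation!r}")
    merged = lads.merged()
    if not len(merged):
        raise ValidationError("no LAD intervals")
    # boundary list: (chrom, position, outward direction on the genome axis)
    bounds: dict[str, list[tuple[int, int]]] = {}
    for iv in merged:
        bounds.setdefault(iv.chrom, []).append((iv.start, -1))  # outward = left
        bounds.setdefault(iv.chrom, []).append((iv.end, +1))    # outward = right
    n_boundaries = sum(len(v) for v in bounds.values())
    half = window // 2
    n_bins = 2 * half // bin_width
    counts = np.zeros(n_bins)
    n_counted = 0
    for g in genes:
        blist = bounds.get(g.chrom)
        if not blist:
            continue
        pos, outward = min(blist, key=lambda b: abs(g.tss - b[0]))
        signed = (g.tss - pos) * outward  # negative = inside the LAD
        if not (-half <= signed < half):
            continue
        gene_dir = +1 if g.strand == "+" else -1
        is_away = gene_dir == outward
        if (orientation == "away") != is_away:
            continue
        counts[(signed + half) // bin_width] += 1.0
        n_counted += 1
    positions = (np.arange(n_bins) + 0.5) * bin_width - half
    return MetaProfile(anchor="LAD-boundary", positions=positions,
                       summary=counts / n_boundaries,
                       spread=np.zeros(n_bins), group=group or orientation,
                       n=n_counted)


def pausing_index(chip_track: BinnedTrack, gene: Gene,
                  tss_window: tuple[int, int] = (-50, 300),
                  body_offset: int = 300,
                  expression_threshold: float = 1.0) -> PausingCall:
    """Promoter-proximal / gene-body occupancy ratio with category call.

    Index = mean density over TSS + tss_window (transcription orientation)
    divided by mean density over [TSS + body_offset, PAS]. Low-expressed
    genes are categorized as such regardless of the index; otherwise
    index >= 2 is paused.
    """
    bw = chip_track.bin_width
    d = +1 if gene.strand == "+" else -1
    lo = gene.tss + d * tss_window[0]
    hi = gene.tss + d * tss_window[1]
    if lo > hi:
        lo, hi = hi, lo
    a0, a1 = chip_track.bin_range(max(0, lo), max(1, hi))
    tss_dens = float(chip_track.values[a0:a1].mean()) if a1 > a0 else 0.0
    blo = gene.tss + d * body_offset
    bhi = gene.pas
    if blo > bhi:
        blo, bhi = bhi, blo
    b0, b1 = chip_track.bin_range(max(0, blo), max(1, bhi))
    body_dens = float(chip_track.values[b0:b1].mean()) if b1 > b0 else 0.0

    if body_dens == 0.0:
        idx = float("inf") if tss_dens > 0 else 0.0
    else:
        idx = tss_dens / body_dens
    if gene.expression < expression_threshold:
        cat = "low-expressed"
    elif idx >= 2.0:
        cat = "paused"
    else:
        cat = "non-paused"
    return PausingCall(gene.id, idx, cat)


def tss_ratio_profile(chip_depleted: dict[tuple[str, str], BinnedTrack],
                      chip_control: dict[tuple[str, str], BinnedTrack],
                      genes: list[Gene], window: int = 4000,
                      eps: float = 0.5, group: str = "") -> MetaProfile:
    """Per-position ratio of group-mean depleted over group-mean control signal.

    Both inputs must be depth-normalized; ``eps`` is added to numerator and
    denominator means to stabilize sparse bins.
    """
    depl = signal_metaplot(chip_depleted, genes, anchor="TSS", window=window,
                           strand_mode="unstranded", summary="mean")
    ctrl = signal_metaplot(chip_control, genes, anchor="TSS", window=window,
                           strand_mode="unstranded", summary="mean")
    ratio = (depl.summary + eps) / (ctrl.summary + eps)
    return MetaProfile(anchor=depl.anchor, positions=depl.positions,
                       summary=ratio, spread=np.zeros(len(ratio)),
                       group=group, n=depl.n)
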