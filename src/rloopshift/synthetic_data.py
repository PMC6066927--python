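"""Toy-genome generator with planted R-loop gains/losses and chromatin context.

Builds a small multi-chromosome genome in which every downstream stage has
known ground truth: genes of four classes (gaining, losing, mixed,
invariant), strand-specific coverage with negative-binomial noise and
planted condition effects, matched chromatin features (heterochromatin
patches, lamina domains, replication origins), per-phase replication-timing
tracks, polymerase occupancy with configurable promoter-proximal pausing,
and Okazaki-strand counts carrying ascending fork-directionality ramps at
planted origins.

Conventions: gaining genes are long, highly expressed and placed on
gene-poor chromosomes with a heterochromatin patch or lamina-domain boundary
a short distance upstream; losing genes are shorter, lowly expressed, placed
on gene-dense chromosomes with an origin overlapping their promoter or
terminator. Gains act on gene-body peaks on the template strand (the gene's
annotated strand); losses act on promoter/terminator peaks. All randomness
flows from integer-keyed generator streams, so outputs are byte-identical
across runs and platforms for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    BinnedTrack,
    FeatureSet,
    Gene,
    GenomicInterval,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_genes_bed12,
)

__all__ = [
    "SimConfig",
    "PlantedPeak",
    "GroundTruth",
    "SimDataset",
    "GenerationError",
    "simulate_dataset",
    "simulate_coverage",
    "simulate_expression_counts",
    "simulate_rnap_chip",
    "simulate_repliseq",
    "simulate_okseq",
    "write_dataset",
]

REPLI_PHASES = ("G1b", "S1", "S2", "S3", "S4", "G2")

# RNG stream keys, combined with the seed for reproducible independent streams
_S_GENES, _S_FEATURES, _S_DEPTH, _S_COVERAGE = 1, 2, 3, 4
_S_EXPRESSION, _S_RNAP, _S_REPLI, _S_OKSEQ = 5, 6, 7, 8


class GenerationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    bin_width: int = 100
    n_genes: int = 500
    frac_rlg: float = 0.12
    frac_rll: float = 0.16
    frac_mixed: float = 0.12
    n_replicates: int = 2

    # coverage noise model
    nb_dispersion: float = 0.05
    background_mean: float = 1.0
    snr: float = 10.0
    gain_log2fc: float = 1.0     # >= log2(1.5)
    loss_log2fc: float = -1.0    # <= log2(0.67)
    depth_sigma: float = 0.15

    # gene geometry (log-normal; medians in bp)
    rlg_len_median: float = 30_000.0
    rlg_len_sigma: float = 0.3
    rll_len_median: float = 8_000.0
    rll_len_sigma: float = 0.3
    mid_len_median: float = 15_000.0
    mid_len_sigma: float = 0.4
    min_gene_gap: int = 6_000
    edge_margin: int = 60_000

    # expression (arbitrary normalized units)
    rlg_expr_median: float = 40.0
    rll_expr_median: float = 5.0
    mid_expr_median: float = 12.0
    expr_sigma: float = 0.35

    # planted peak geometry
    promoter_peak_len: int = 1_500
    body_peak_len: int = 4_000
    tail_fraction: float = 0.3
    tail_length: int = 1_500

    # chromatin feature placement probabilities per gene class
    h3k9_prob: dict = field(default_factory=lambda: {
        "RLG": 0.8, "mixed": 0.2, "none": 0.2, "RLL": 0.02})
    lad_prob: dict = field(default_factory=lambda: {
        "RLG": 0.5, "mixed": 0.08, "none": 0.08, "RLL": 0.02})
    origin_prob: dict = field(default_factory=lambda: {
        "RLL": 0.9, "mixed": 0.25, "none": 0.25, "RLG": 0.02})
    h3k27_prob: dict = field(default_factory=lambda: {
        "RLL": 0.5, "mixed": 0.1, "none": 0.1, "RLG": 0.05})
    feature_distance: int = 10_000
    origin_width: int = 3_000
    n_blacklist_per_chrom: int = 2
    blacklist_width: int = 20_000

    # pausing and expression changes
    paused_prob: dict = field(default_factory=lambda: {
        "RLG": 0.6, "mixed": 0.15, "none": 0.15, "RLL": 0.05})
    pausing_factor: float = 5.0
    depleted_tss_factor: float = 1.6
    de_fraction: float = 0.03

    # replication timing: distance from an origin at which a locus is fully
    # late-replicating
    repli_timing_scale: int = 300_000

    # fork directionality
    rfd_bin_width: int = 1_000
    okseq_depth: int = 150
    rfd_amplitude: float = 0.8
    rfd_ramp_halfwidth: int = 15_000

    def __post_init__(self):
        if self.frac_rlg + self.frac_rll + self.frac_mixed > 1.0:
            raise ValueError("class fractions must sum to <= 1")
        for name in ("chrom_length", "bin_width", "n_genes", "background_mean",
                     "snr", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def sample_names(self) -> list[str]:
        return [f"{cond}_{r}" for cond in ("control", "depleted")
                for r in range(1, self.n_replicates + 1)]

    def conditions(self) -> dict[str, str]:
        return {s: s.split("_")[0] for s in self.sample_names()}


@dataclass(frozen=True)
class PlantedPeak:
    id: str
    interval: GenomicInterval
    gene_id: str
    compartment: str  # promoter | body | terminator
    log2fc: float
    has_tail: bool = False

    @property
    def chrom(self):
        return self.interval.chrom

    @property
    def start(self):
        return self.interval.start

    @property
    def end(self):
        return self.interval.end

    @property
    def strand(self):
        return self.interval.strand


@dataclass
class GroundTruth:
    gene_classes: dict[str, str]
    peaks: list[PlantedPeak]
    depth_factors: dict[str, float]
    paused: dict[str, bool]
    de_log2fc: dict[str, float]


@dataclass
class SimDataset:
    config: SimConfig
    chrom_sizes: dict[str, int]
    genes: list[Gene]
    features: dict[str, FeatureSet]
    truth: GroundTruth


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([seed, *keys])


def _lognormal_lengths(rng, median, sigma, n, minimum=1_000):
    vals = np.exp(np.log(median) + sigma * rng.standard_normal(n))
    return np.maximum(vals.astype(np.int64), minimum)


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> SimDataset:
    """Place genes, plant peaks and chromatin features; record ground truth.

    Gene-dense chromosomes (the first half) host the losing genes, gene-poor
    chromosomes the gaining genes; the unaffected pool is split so each side
    has matched candidates of comparable geometry. Raises GenerationError if
    the requested genes cannot fit.
    """
    cfg = config
    rng = _rng(cfg.seed, _S_GENES)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_sizes = {c: cfg.chrom_length for c in chroms}
    n_dense = max(1, cfg.n_chroms // 2)
    dense, sparse = chroms[:n_dense], chroms[n_dense:] or chroms[:1]

    n_rlg = int(round(cfg.n_genes * cfg.frac_rlg))
    n_rll = int(round(cfg.n_genes * cfg.frac_rll))
    n_mixed = int(round(cfg.n_genes * cfg.frac_mixed))
    n_none = cfg.n_genes - n_rlg - n_rll - n_mixed
    # unaffected pool: a modest share mirrors gaining-gene geometry (matched
    # candidates, placed on the sparse chromosomes), the rest sits on dense
    # chromosomes; keeping the sparse side lightly occupied preserves the
    # isolation contrast between gaining and losing genes
    n_none_sparse = n_none // 6
    n_mixed_sparse = n_mixed // 3

    specs = []  # (class, side, len_median, len_sigma, expr_median)
    specs += [("RLG", "sparse", cfg.rlg_len_median, cfg.rlg_len_sigma,
               cfg.rlg_expr_median)] * n_rlg
    specs += [("none", "sparse", cfg.rlg_len_median, cfg.rlg_len_sigma,
               cfg.rlg_expr_median)] * n_none_sparse
    specs += [("mixed", "sparse", cfg.rlg_len_median, cfg.rlg_len_sigma,
               cfg.rlg_expr_median)] * n_mixed_sparse
    specs += [("RLL", "dense", cfg.rll_len_median, cfg.rll_len_sigma,
               cfg.rll_expr_median)] * n_rll
    specs += [("mixed", "dense", cfg.rll_len_median, cfg.rll_len_sigma,
               cfg.rll_expr_median)] * (n_mixed - n_mixed_sparse)
    n_none_dense = n_none - n_none_sparse
    n_none_rll_like = n_none_dense // 2
    specs += [("none", "dense", cfg.rll_len_median, cfg.rll_len_sigma,
               cfg.rll_expr_median)] * n_none_rll_like
    specs += [("none", "dense", cfg.mid_len_median, cfg.mid_len_sigma,
               cfg.mid_expr_median)] * (n_none_dense - n_none_rll_like)

    lengths = np.array([
        _lognormal_lengths(rng, m, s, 1)[0] for (_, _, m, s, _) in specs
    ])
    exprs = np.array([
        float(np.exp(np.log(e) + cfg.expr_sigma * rng.standard_normal()))
        for (_, _, _, _, e) in specs
    ])
    strands = rng.choice(["+", "-"], size=len(specs))

    # distribute each side's genes over its chromosomes, then fill each
    # chromosome left-to-right with rng-drawn gaps scaled to fit exactly
    side_idx = {"dense": [i for i, s in enumerate(specs) if s[1] == "dense"],
                "sparse": [i for i, s in enumerate(specs) if s[1] == "sparse"]}
    gene_chrom = [""] * len(specs)
    for side, chrom_list in (("dense", dense), ("sparse", sparse)):
        idxs = side_idx[side]
        perm = rng.permutation(len(idxs))
        for j, pi in enumerate(perm):
            gene_chrom[idxs[pi]] = chrom_list[j % len(chrom_list)]

    genes: list[Gene] = []
    classes: dict[str, str] = {}
    order = 0
    for chrom in chroms:
        members = [i for i in range(len(specs)) if gene_chrom[i] == chrom]
        rng.shuffle(members)
        total_len = int(lengths[members].sum())
        usable = cfg.chrom_length - 2 * cfg.edge_margin
        slack = usable - total_len - cfg.min_gene_gap * (len(members) + 1)
        if slack < 0:
            raise GenerationError(
                f"{chrom}: genes do not fit; reduce n_genes or gene lengths")
        raw_gaps = rng.exponential(1.0, size=len(members) + 1)
        gaps = cfg.min_gene_gap + raw_gaps / raw_gaps.sum() * slack
        pos = cfg.edge_margin
        for k, gi in enumerate(members):
            pos += int(gaps[k])
            gid = f"g{order:04d}"
            order += 1
            iv = GenomicInterval(chrom, pos, pos + int(lengths[gi]),
                                 str(strands[gi]))
            genes.append(Gene(gid, iv, float(exprs[gi])))
            classes[gid] = specs[gi][0]
            pos = iv.end
    genes.sort(key=lambda g: (g.chrom, g.start))

    peaks = _plant_peaks(cfg, genes, classes, rng)
    features, paused = _place_features(cfg, genes, classes, chrom_sizes)
    depth_rng = _rng(cfg.seed, _S_DEPTH)
    depth = {s: float(np.exp(cfg.depth_sigma * depth_rng.standard_normal()))
             for s in cfg.sample_names()}
    de_rng = _rng(cfg.seed, _S_EXPRESSION, 0)
    de: dict[str, float] = {}
    for g in genes:
        if de_rng.random() < cfg.de_fraction:
            de[g.id] = float(de_rng.choice([-1.0, 1.0]))

    truth = GroundTruth(classes, peaks, depth, paused, de)
    return SimDataset(cfg, chrom_sizes, genes, features, truth)


def _plant_peaks(cfg: SimConfig, genes, classes, rng) -> list[PlantedPeak]:
    peaks: list[PlantedPeak] = []
    counter = 0

    def add(iv, gid, comp, lfc, tail=False):
        nonlocal counter
        peaks.append(PlantedPeak(f"tp{counter:05d}", iv, gid, comp, lfc, tail))
        counter += 1

    for g in genes:
        cls = classes[g.id]
        d = +1 if g.strand == "+" else -1
        # promoter peak straddling the TSS, biased downstream
        pl = cfg.promoter_peak_len
        p0 = g.tss - d * (pl // 6) if d > 0 else g.tss - (pl - pl // 6)
        prom = GenomicInterval(g.chrom, max(0, p0), max(0, p0) + pl, g.strand)
        t0 = g.pas - (pl - pl // 6) if d > 0 else g.pas - pl // 6
        term = GenomicInterval(g.chrom, max(0, t0), max(0, t0) + pl, g.strand)
        # body peaks at fixed fractional positions inside the gene
        n_body = min(3, 1 + g.length // 30_000)
        body_ivs = []
        body_len = min(cfg.body_peak_len, max(600, g.length // 4))
        for k in range(n_body):
            frac = (k + 1) / (n_body + 1)
            center = g.start + int(g.length * frac)
            b0 = max(g.start + pl, center - body_len // 2)
            b1 = min(g.end - pl, b0 + body_len)
            if b1 - b0 >= 300:
                body_ivs.append(GenomicInterval(g.chrom, b0, b1, g.strand))

        gain = cfg.gain_log2fc
        loss = cfg.loss_log2fc
        if cls == "RLG":
            add(prom, g.id, "promoter", 0.0)
            for iv in body_ivs:
                add(iv, g.id, "body", gain, tail=rng.random() < cfg.tail_fraction)
            add(term, g.id, "terminator", 0.0)
        elif cls == "RLL":
            add(prom, g.id, "promoter", loss)
            for iv in body_ivs:
                add(iv, g.id, "body", 0.0)
            add(term, g.id, "terminator", loss)
        elif cls == "mixed":
            add(prom, g.id, "promoter", loss)
            for k, iv in enumerate(body_ivs):
                add(iv, g.id, "body", gain if k == 0 else 0.0)
            add(term, g.id, "terminator", 0.0)
        else:
            add(prom, g.id, "promoter", 0.0)
            for iv in body_ivs:
                add(iv, g.id, "body", 0.0,
                    tail=rng.random() < cfg.tail_fraction)
            add(term, g.id, "terminator", 0.0)
    return peaks


def _place_features(cfg: SimConfig, genes, classes, chrom_sizes):
    rng = _rng(cfg.seed, _S_FEATURES)
    h3k9, lads, origins, h3k27 = [], [], [], []
    paused: dict[str, bool] = {}
    for g in genes:
        cls = classes[g.id]
        d = +1 if g.strand == "+" else -1
        limit = chrom_sizes[g.chrom]
        paused[g.id] = bool(rng.random() < cfg.paused_prob[cls])
        if rng.random() < cfg.h3k9_prob[cls]:
            width = int(rng.uniform(5_000, 15_000))
            gap = int(rng.uniform(0, cfg.feature_distance))
            if d > 0:
                s, e = g.tss - gap - width, g.tss - gap
            else:
                s, e = g.tss + gap, g.tss + gap + width
            if 0 <= s < e <= limit:
                h3k9.append(GenomicInterval(g.chrom, s, e))
        if rng.random() < cfg.lad_prob[cls]:
            # toy-scale lamina domain ending near (occasionally just past)
            # the TSS so the gene transcribes away from the domain interior
            width = int(rng.uniform(30_000, 80_000))
            gap = int(rng.uniform(-2_000, cfg.feature_distance))
            if d > 0:
                s, e = g.tss - gap - width, g.tss - gap
            else:
                s, e = g.tss + gap, g.tss + gap + width
            s, e = max(0, s), min(limit, e)
            if e > s:
                lads.append(GenomicInterval(g.chrom, s, e))
        if rng.random() < cfg.origin_prob[cls]:
            anchor = g.tss if rng.random() < 0.5 else g.pas
            s = max(0, anchor - cfg.origin_width // 2)
            e = min(limit, s + cfg.origin_width)
            origins.append(GenomicInterval(g.chrom, s, e))
        if rng.random() < cfg.h3k27_prob[cls]:
            s = max(0, g.tss - 2_000)
            e = min(limit, g.tss + 2_000)
            h3k27.append(GenomicInterval(g.chrom, s, e))

    blacklist = []
    gene_spans = {}
    for g in genes:
        gene_spans.setdefault(g.chrom, []).append((g.start - 5_000, g.end + 5_000))
    for chrom, size in chrom_sizes.items():
        spans = sorted(gene_spans.get(chrom, []))
        placed = 0
        for _ in range(200):
            if placed >= cfg.n_blacklist_per_chrom:
                break
            s = int(rng.uniform(0, size - cfg.blacklist_width))
            e = s + cfg.blacklist_width
            if any(s < b and a < e for a, b in spans):
                continue
            blacklist.append(GenomicInterval(chrom, s, e))
            placed += 1

    features = {
        "H3K9me3": FeatureSet("H3K9me3", h3k9).sorted(),
        "LAD": FeatureSet("LAD", lads).merged(),
        "SNS_origin": FeatureSet("SNS_origin", origins).sorted(),
        "H3K27me3": FeatureSet("H3K27me3", h3k27).sorted(),
        "blacklist": FeatureSet("blacklist", blacklist).sorted(),
    }
    return features, paused


# ---------------------------------------------------------------------------
# Coverage and auxiliary tracks
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-9)
    if dispersion < 1e-9:
        return rng.poisson(mean).astype(float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def simulate_coverage(dataset: SimDataset, condition: str, replicate: int,
                      seed: int | None = None,
                      ) -> tuple[dict[tuple[str, str], BinnedTrack], float]:
    """Strand-specific binned counts for one sample.

    Background bins are NB with a low mean; planted peak bins are NB with
    mean background * SNR, multiplied (gains) or divided (losses) by the
    planted effect in the depleted condition only; decaying tails extend a
    configurable distance past tailed peaks. The sample's depth factor
    scales every mean. Returns the tracks and the mapped-read total.
    """
    cfg = dataset.config
    if condition not in ("control", "depleted"):
        raise ValueError(f"unknown condition {condition!r}")
    seed = cfg.seed if seed is None else seed
    cond_idx = 0 if condition == "control" else 1
    rng = _rng(seed, _S_COVERAGE, cond_idx, replicate)
    sample = f"{condition}_{replicate}"
    depth = dataset.truth.depth_factors[sample]
    bw = cfg.bin_width

    means: dict[tuple[str, str], np.ndarray] = {}
    for chrom, size in dataset.chrom_sizes.items():
        n_bins = math.ceil(size / bw)
        for strand in ("+", "-"):
            means[(chrom, strand)] = np.full(n_bins, cfg.background_mean)

    for p in dataset.truth.peaks:
        effect = 2.0 ** p.log2fc if condition == "depleted" else 1.0
        arr = means[(p.chrom, p.strand)]
        lo, hi = p.start // bw, -(-p.end // bw)
        arr[lo:hi] = cfg.background_mean * cfg.snr * effect
        if p.has_tail:
            # exponential decay on the 3' side of the peak
            n_tail = cfg.tail_length // bw
            scale = cfg.tail_length / 3.0
            offs = (np.arange(n_tail) + 0.5) * bw
            tail = 1.0 + (cfg.snr * effect - 1.0) * np.exp(-offs / scale)
            if p.strand == "+":
                sl = slice(hi, min(hi + n_tail, len(arr)))
                arr[sl] = np.maximum(arr[sl], cfg.background_mean * tail[:sl.stop - sl.start])
            else:
                sl = slice(max(0, lo - n_tail), lo)
                arr[sl] = np.maximum(
                    arr[sl], cfg.background_mean * tail[:sl.stop - sl.start][::-1])

    tracks: dict[tuple[str, str], BinnedTrack] = {}
    total = 0.0
    for (chrom, strand) in sorted(means):
        counts = _nb_draw(rng, means[(chrom, strand)] * depth, cfg.nb_dispersion)
        total += float(counts.sum())
        tracks[(chrom, strand)] = BinnedTrack(
            chrom=chrom, bin_width=bw, strand=strand, values=counts,
            chrom_length=dataset.chrom_sizes[chrom])
    for tr in tracks.values():
        tr.mapped_read_total = total
    return tracks, total


def simulate_expression_counts(dataset: SimDataset) -> pd.DataFrame:
    """Gene-level RNA-seq-like counts per sample (rows = genes)."""
    cfg = dataset.config
    rng = _rng(cfg.seed, _S_EXPRESSION, 1)
    samples = cfg.sample_names()
    data = np.zeros((len(dataset.genes), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        depth = dataset.truth.depth_factors[s]
        cond = s.split("_")[0]
        for i, g in enumerate(dataset.genes):
            mean = g.expression * (g.length / 1_000.0) * depth
            if cond == "depleted" and g.id in dataset.truth.de_log2fc:
                mean *= 2.0 ** dataset.truth.de_log2fc[g.id]
            data[i, j] = int(_nb_draw(rng, np.array([mean]), 0.02)[0])
    return pd.DataFrame(data, index=[g.id for g in dataset.genes],
                        columns=samples)


def simulate_rnap_chip(dataset: SimDataset, condition: str,
                       ) -> dict[tuple[str, str], BinnedTrack]:
    """Unstranded polymerase occupancy with promoter-proximal pausing.

    Body coverage scales with expression; paused genes carry an elevated
    TSS-proximal window that grows further under depletion.
    """
    cfg = dataset.config
    cond_idx = 0 if condition == "control" else 1
    rng = _rng(cfg.seed, _S_RNAP, cond_idx)
    bw = cfg.bin_width
    tracks = {}
    for chrom, size in sorted(dataset.chrom_sizes.items()):
        n_bins = math.ceil(size / bw)
        mean = np.full(n_bins, 0.2)
        for g in dataset.genes:
            if g.chrom != chrom:
                continue
            body = 0.05 * g.expression
            lo, hi = g.start // bw, -(-g.end // bw)
            mean[lo:hi] += body
            d = +1 if g.strand == "+" else -1
            w0, w1 = sorted((g.tss - d * 50, g.tss + d * 300))
            lo, hi = max(0, w0) // bw, -(-max(1, w1) // bw)
            factor = cfg.pausing_factor if dataset.truth.paused[g.id] else 1.2
            if condition == "depleted" and dataset.truth.paused[g.id]:
                factor *= cfg.depleted_tss_factor
            mean[lo:hi] += body * (factor - 1.0)
        counts = rng.poisson(mean).astype(float)
        tracks[(chrom, ".")] = BinnedTrack(chrom=chrom, bin_width=bw,
                                           strand=".", values=counts,
                                           chrom_length=size,
                                           mapped_read_total=float(counts.sum()))
    total = sum(t.mapped_read_total for t in tracks.values())
    for t in tracks.values():
        t.mapped_read_total = total
    return tracks


def simulate_repliseq(dataset: SimDataset) -> dict[str, dict[str, BinnedTrack]]:
    """Six per-phase tracks; loci near origins replicate early."""
    cfg = dataset.config
    rng = _rng(cfg.seed, _S_REPLI)
    bw = cfg.bin_width * 10  # coarser bins are plenty for timing
    origin_centers = {}
    for iv in dataset.features["SNS_origin"]:
        origin_centers.setdefault(iv.chrom, []).append((iv.start + iv.end) // 2)
    out: dict[str, dict[str, BinnedTrack]] = {ph: {} for ph in REPLI_PHASES}
    for chrom, size in sorted(dataset.chrom_sizes.items()):
        n_bins = math.ceil(size / bw)
        centers = np.asarray(sorted(origin_centers.get(chrom, [])), dtype=float)
        x = (np.arange(n_bins) + 0.5) * bw
        if len(centers):
            idx = np.searchsorted(centers, x)
            left = np.where(idx > 0, np.abs(x - centers[np.maximum(idx - 1, 0)]),
                            np.inf)
            right = np.where(idx < len(centers),
                             np.abs(centers[np.minimum(idx, len(centers) - 1)] - x),
                             np.inf)
            dist = np.minimum(left, right)
        else:
            dist = np.full(n_bins, np.inf)
        scale = float(cfg.repli_timing_scale)
        timing = 5.0 * np.minimum(np.where(np.isfinite(dist), dist, scale),
                                  scale) / scale
        for k, ph in enumerate(REPLI_PHASES):
            weight = np.exp(-((timing - k) ** 2) / (2 * 0.75 ** 2))
            counts = rng.poisson(5.0 * weight).astype(float)
            out[ph][chrom] = BinnedTrack(chrom=chrom, bin_width=bw, strand=".",
                                         values=counts, chrom_length=size,
                                         mapped_read_total=float(counts.sum()) or 1.0)
    return out


def rfd_origin_centers(dataset: SimDataset, chrom: str) -> list[int]:
    """Origin centers carrying a fork-directionality ramp.

    Clustered origins fire as one initiation zone: centers are greedily
    thinned to a minimum spacing of 4x the ramp half-width so each ramp is
    individually resolvable.
    """
    cfg = dataset.config
    centers = sorted({(iv.start + iv.end) // 2
                      for iv in dataset.features["SNS_origin"]
                      if iv.chrom == chrom})
    spacing = 4 * cfg.rfd_ramp_halfwidth
    kept: list[int] = []
    for c in centers:
        if not kept or c - kept[-1] >= spacing:
            kept.append(c)
    return kept


def true_rfd(dataset: SimDataset, chrom: str) -> np.ndarray:
    """Noise-free sawtooth fork directionality for one chromosome.

    Ascending ramps are centered on (thinned) planted origins; between
    consecutive origins the signal decays linearly back down.
    """
    cfg = dataset.config
    bw = cfg.rfd_bin_width
    size = dataset.chrom_sizes[chrom]
    n_bins = math.ceil(size / bw)
    x = (np.arange(n_bins) + 0.5) * bw
    centers = rfd_origin_centers(dataset, chrom)
    if not centers:
        return np.zeros(n_bins)
    a, h = cfg.rfd_amplitude, cfg.rfd_ramp_halfwidth
    rfd = np.zeros(n_bins)
    pts = [0] + [int(c) for c in centers] + [size]
    for i, c in enumerate(centers):
        ramp = np.clip((x - c) / h, -1, 1) * a
        # restrict each origin's ramp to its midpoint-bounded neighborhood
        lo = (pts[i] + c) // 2 if i > 0 else 0
        hi = (c + pts[i + 2]) // 2 if i < len(centers) - 1 else size
        sel = (x >= lo) & (x < hi)
        rfd[sel] = ramp[sel]
    return rfd


def simulate_okseq(dataset: SimDataset) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (crick, watson) strand counts carrying the RFD sawtooth."""
    cfg = dataset.config
    rng = _rng(cfg.seed, _S_OKSEQ)
    out = {}
    for chrom in sorted(dataset.chrom_sizes):
        rfd = true_rfd(dataset, chrom)
        p_crick = (1.0 + rfd) / 2.0
        n = rng.poisson(cfg.okseq_depth, size=len(rfd))
        crick = rng.binomial(n, p_crick).astype(float)
        watson = (n - crick).astype(float)
        out[chrom] = (crick, watson)
    return out


# ---------------------------------------------------------------------------
# On-disk emission
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimDataset, outdir) -> dict[str, str]:
    """Emit the dataset as plain-text files and return the manifest.

    Coverage is one bedGraph per strand per sample; features are BED; genes
    are BED12; expression and ground truth are TSV. The manifest maps file
    name to role.
    """
    cfg = dataset.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    write_chrom_sizes(dataset.chrom_sizes, outdir / "genome.chrom.sizes")
    manifest["genome.chrom.sizes"] = "chromosome sizes"
    write_genes_bed12(dataset.genes, outdir / "genes.bed12")
    manifest["genes.bed12"] = "gene annotation"

    for name, fs in sorted(dataset.features.items()):
        fn = f"feature_{name}.bed"
        write_bed(fs.intervals, outdir / fn)
        manifest[fn] = f"feature set {name}"

    totals = {}
    for sample in cfg.sample_names():
        cond, rep = sample.rsplit("_", 1)
        tracks, total = simulate_coverage(dataset, cond, int(rep))
        totals[sample] = total
        for strand, tag in (("+", "plus"), ("-", "minus")):
            fn = f"dripc_{sample}.{tag}.bedgraph"
            write_bedgraph({c: tracks[(c, strand)]
                            for c in dataset.chrom_sizes}, outdir / fn)
            manifest[fn] = f"strand-specific coverage {sample} ({strand})"

    with open(outdir / "mapped_totals.tsv", "w") as fh:
        fh.write("sample\tmapped_read_total\tdepth_factor\n")
        for s in cfg.sample_names():
            fh.write(f"{s}\t{totals[s]:.0f}\t{dataset.truth.depth_factors[s]:.6f}\n")
    manifest["mapped_totals.tsv"] = "per-sample mapped-read totals"

    expr = simulate_expression_counts(dataset)
    expr.to_csv(outdir / "expression_counts.tsv", sep="\t")
    manifest["expression_counts.tsv"] = "gene expression counts"

    for cond in ("control", "depleted"):
        tracks = simulate_rnap_chip(dataset, cond)
        fn = f"rnap_{cond}.bedgraph"
        write_bedgraph({c: tracks[(c, ".")] for c in dataset.chrom_sizes},
                       outdir / fn)
        manifest[fn] = f"polymerase occupancy ({cond})"

    repli = simulate_repliseq(dataset)
    for ph in REPLI_PHASES:
        fn = f"repli_{ph}.bedgraph"
        write_bedgraph(repli[ph], outdir / fn)
        manifest[fn] = f"replication timing phase {ph}"

    okseq = simulate_okseq(dataset)
    for tag, col in (("crick", 0), ("watson", 1)):
        fn = f"okseq_{tag}.bedgraph"
        with open(outdir / fn, "w") as fh:
            for chrom in sorted(okseq):
                vals = okseq[chrom][col]
                bw = cfg.rfd_bin_width
                for i, v in enumerate(vals):
                    if v:
                        fh.write(f"{chrom}\t{i * bw}\t{min((i + 1) * bw, dataset.chrom_sizes[chrom])}\t{v:g}\n")
        manifest[fn] = f"Okazaki strand counts ({tag})"

    rows = []
    for g in dataset.genes:
        rows.append({
            "gene_id": g.id, "chrom": g.chrom, "start": g.start, "end": g.end,
            "strand": g.strand, "length": g.length,
            "expression": g.expression,
            "rl_class": dataset.truth.gene_classes[g.id],
            "paused": int(dataset.truth.paused[g.id]),
            "de_log2fc": dataset.truth.de_log2fc.get(g.id, 0.0),
        })
    pd.DataFrame(rows).to_csv(outdir / "ground_truth_genes.tsv", sep="\t",
                              index=False)
    manifest["ground_truth_genes.tsv"] = "per-gene ground truth"

    rows = [{
        "peak_id": p.id, "chrom": p.chrom, "start": p.start, "end": p.end,
        "strand": p.strand, "gene_id": p.gene_id,
        "compartment": p.compartment, "log2fc": p.log2fc,
        "has_tail": int(p.has_tail),
    } for p in dataset.truth.peaks]
    pd.DataFrame(rows).to_csv(outdir / "ground_truth_peaks.tsv", sep="\t",
                              index=False)
    manifest["ground_truth_peaks.tsv"] = "planted peak ground truth"

    with open(outdir / "MANIFEST.tsv", "w") as fh:
        fh.write("file\trole\n")
        for fn in sorted(manifest):
            fh.write(f"{fn}\t{manifest[fn]}\n")
    return manifest
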