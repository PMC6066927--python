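"""Matched-control Monte-Carlo enrichment, distances and fold-change binning.

Target peaks (on gaining or losing genes) are matched to control peaks on
unaffected R-loop-forming genes of similar expression, gene length, peak
length and genic compartment. Feature enrichment is the observed overlap
fraction against the mean over resampled control sets, with an empirical
Monte-Carlo p-value (1 + exceedances) / (1 + randomizations).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BinnedTrack, FeatureSet, Gene, GenomicInterval, ValidationError
from .diff_rloop import peak_compartment
from .peakcall_hmm import Peak

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedPeak",
    "MatchedControlSet",
    "EnrichmentResult",
    "FoldChangeBin",
    "annotate_peaks",
    "select_matched_controls",
    "overlap_enrichment",
    "distance_to_nearest",
    "compare_distance_sets",
    "foldchange_bins",
    "repliseq_phase_assignment",
    "phase_distribution_mc",
]

REPLI_PHASES = ("G1b", "S1", "S2", "S3", "S4", "G2")


@dataclass(frozen=True)
class AnnotatedPeak:
    """A peak annotated with its host gene's covariates."""

    peak: Peak
    gene_id: str
    gene_class: str
    compartment: str  # promoter | body | terminator | intergenic
    gene_length: int
    expression: float
    offset: int  # strand-aware offset of the peak 5' edge from its anchor

    @property
    def id(self) -> str:
        return self.peak.id

    @property
    def interval(self) -> GenomicInterval:
        return self.peak.interval


@dataclass
class MatchedControlSet:
    """target peak id -> matched control peaks, with matching metadata."""

    targets: dict[str, AnnotatedPeak]
    controls: dict[str, list[AnnotatedPeak]]
    tolerance_used: dict[str, float]
    dropped: list[str] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    feature: str
    label: str
    observed: float
    expected: float
    ratio: float
    star: str  # '' | * | ** | ***
    p_value: float
    p_enrich: float
    p_deplete: float
    flagged: bool = False


@dataclass
class FoldChangeBin:
    index: int
    peak_ids: list[str]
    median_covariate: float
    median_log2fc: float


def _anchor(gene: Gene, compartment: str) -> int:
    return gene.pas if compartment == "terminator" else gene.tss


def annotate_peaks(peaks: list[Peak], genes: list[Gene],
                   gene_classes: dict[str, str],
                   flank: int = 2000) -> list[AnnotatedPeak]:
    """Attach each peak to the overlapping gene with the largest overlap.

    Peaks with no strand-matched overlapping gene (within ``flank``) are
    annotated as intergenic with gene covariates of 0 and are unusable for
    gene-matched control selection.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[AnnotatedPeak] = []
    for p in peaks:
        best, best_ov = None, 0
        for g in by_chrom.get(p.chrom, []):
            if p.strand != "." and g.strand != "." and p.strand != g.strand:
                continue
            ov = min(p.end, g.end + flank) - max(p.start, g.start - flank)
            if ov > best_ov:
                best, best_ov = g, ov
        if best is None:
            out.append(AnnotatedPeak(p, "", "none", "intergenic", 0, 0.0, 0))
            continue
        comp = peak_compartment(p, best, flank=flank)
        if comp == "intergenic":
            comp = "body"  # attached gene but outside anchors: treat as body
        anchor = _anchor(best, comp)
        offset = (p.start - anchor) if best.strand == "+" else (anchor - p.end)
        out.append(AnnotatedPeak(p, best.id, gene_classes.get(best.id, "none"),
                                 comp, best.length, best.expression, offset))
    return out


def select_matched_controls(targets: list[AnnotatedPeak],
                            candidates: list[AnnotatedPeak],
                            tol_len: float = 0.5, tol_expr: float = 0.5,
                            tol_peak: float = 0.5, n_matches: int = 10,
                            seed: int = 0, max_relax: int = 3,
                            chrom_sizes: dict[str, int] | None = None,
                            ) -> MatchedControlSet:
    """Sample expression/length/compartment-matched control peaks per target.

    Candidates must lie on genes of class none or mixed. Tolerances are in
    log2 units and are doubled stepwise (up to ``max_relax`` times, with a
    warning) when fewer than ``n_matches`` candidates qualify; targets that
    still cannot be matched are dropped and logged. For promoter and
    terminator targets the control peak keeps its own length but is
    re-positioned to the target's offset relative to the control gene's
    TSS/PAS, so the position relative to the anchor is maintained.
    """
    rng = np.random.default_rng(seed)
    pool = [c for c in candidates
            if c.gene_class in ("none", "mixed") and c.gene_id]
    out = MatchedControlSet({}, {}, {})
    for t in sorted(targets, key=lambda t: t.id):
        if not t.gene_id:
            out.dropped.append(t.id)
            continue
        chosen: list[AnnotatedPeak] = []
        tol = 1.0
        for attempt in range(max_relax + 1):
            tl, te, tp = tol_len * tol, tol_expr * tol, tol_peak * tol
            eligible = [
                c for c in pool
                if c.compartment == t.compartment
                and c.gene_id != t.gene_id
                and abs(_log2r(c.gene_length, t.gene_length)) <= tl
                and abs(_log2r(c.expression, t.expression)) <= te
                and abs(_log2r(c.peak.interval.length, t.peak.interval.length)) <= tp
            ]
            if len(eligible) >= n_matches:
                idx = rng.choice(len(eligible), size=n_matches, replace=False)
                chosen = [eligible[i] for i in sorted(idx)]
                break
            tol *= 2.0
        else:
            out.dropped.append(t.id)
            logger.info("target %s dropped: no matches at maximum relaxation", t.id)
            continue
        if attempt > 0:
            logger.info("target %s matched at %dx relaxed tolerances", t.id, 2 ** attempt)
        if t.compartment in ("promoter", "terminator"):
            chosen = [_repositioned(c, t.offset, chrom_sizes) for c in chosen]
            chosen = [c for c in chosen if c is not None]
            if not chosen:
                out.dropped.append(t.id)
                continue
        out.targets[t.id] = t
        out.controls[t.id] = chosen
        out.tolerance_used[t.id] = tol
    return out


def _log2r(a: float, b: float) -> float:
    return math.log2((a + 1e-9) / (b + 1e-9))


def _repositioned(ctrl: AnnotatedPeak, offset: int,
                  chrom_sizes: dict[str, int] | None) -> AnnotatedPeak | None:
    """Place the control peak at ``offset`` from its own gene anchor."""
    iv = ctrl.peak.interval
    length = iv.length
    # reconstruct the control gene anchor from the control's own offset
    if iv.strand == "-":
        anchor = iv.end + ctrl.offset
        end = anchor - offset
        start = end - length
    else:
        anchor = iv.start - ctrl.offset
        start = anchor + offset
        end = start + length
    limit = chrom_sizes.get(iv.chrom) if chrom_sizes else None
    if start < 0 or (limit is not None and end > limit) or end <= start:
        return None
    new_peak = Peak(GenomicInterval(iv.chrom, start, end, iv.strand),
                    sample=ctrl.peak.sample, id=ctrl.peak.id)
    return AnnotatedPeak(new_peak, ctrl.gene_id, ctrl.gene_class,
                         ctrl.compartment, ctrl.gene_length, ctrl.expression,
                         offset)


# ---------------------------------------------------------------------------
# Overlap machinery
# ---------------------------------------------------------------------------

def _overlaps_any(iv: GenomicInterval, arrs: dict[str, np.ndarray]) -> bool:
    arr = arrs.get(iv.chrom)
    if arr is None or not len(arr):
        return False
    idx = np.searchsorted(arr[:, 0], iv.end)
    return bool(idx > 0 and arr[idx - 1, 1] > iv.start)


def star_class(observed: float) -> str:
    """Absolute-overlap star class: <10% none, 10-25% *, 25-50% **, >50% ***."""
    if observed < 0.10:
        return ""
    if observed < 0.25:
        return "*"
    if observed <= 0.50:
        return "**"
    return "***"


def _mc_stats(matched: MatchedControlSet, per_peak_stat, n_mc: int,
              rng: np.random.Generator):
    """Observed statistic and n_mc resampled control-set statistics.

    ``per_peak_stat`` maps an AnnotatedPeak to a float; set-level statistic
    is the mean over peaks.
    """
    tids = sorted(matched.targets)
    obs_vals = np.array([per_peak_stat(matched.targets[t]) for t in tids])
    n_matches = min(len(matched.controls[t]) for t in tids)
    ctrl_mat = np.array([[per_peak_stat(c)
                          for c in matched.controls[t][:n_matches]]
                         for t in tids])
    observed = float(obs_vals.mean())
    picks = rng.integers(0, n_matches, size=(n_mc, len(tids)))
    draws = ctrl_mat[np.arange(len(tids))[None, :], picks].mean(axis=1)
    return observed, draws


def overlap_enrichment(matched: MatchedControlSet, feature: FeatureSet,
                       n_mc: int = 249, seed: int = 0,
                       label: str = "") -> EnrichmentResult:
    """Observed/expected feature-overlap fraction with Monte-Carlo p.

    p_enrich = (1 + #{control sets with fraction >= observed}) / (1 + n_mc),
    mirrored for depletion; the reported two-sided p is 2*min of the two,
    capped at 1. Overlap is any-overlap (>= 1 bp).
    """
    if not matched.targets:
        raise ValidationError("matched set has no targets")
    arrs = feature.by_chrom()
    if not arrs:
        return EnrichmentResult(feature.name, label, math.nan, math.nan,
                                math.nan, "", 1.0, 1.0, 1.0, flagged=True)
    rng = np.random.default_rng(seed)
    observed, draws = _mc_stats(
        matched, lambda ap: float(_overlaps_any(ap.interval, arrs)), n_mc, rng)
    expected = float(draws.mean())
    p_enr = (1 + int((draws >= observed).sum())) / (1 + n_mc)
    p_dep = (1 + int((draws <= observed).sum())) / (1 + n_mc)
    p_two = min(1.0, 2.0 * min(p_enr, p_dep))
    ratio = observed / expected if expected > 0 else math.inf
    return EnrichmentResult(feature.name, label, observed, expected, ratio,
                            star_class(observed), p_two, p_enr, p_dep,
                            flagged=expected == 0)


def distance_to_nearest(peaks, feature: FeatureSet) -> np.ndarray:
    """Edge-to-edge distance from each peak to the nearest feature interval.

    Overlap gives 0; chromosomes with no feature give +inf (callers exclude
    and count those). Strand-agnostic; sorted-sweep over merged intervals.
    """
    arrs = feature.by_chrom()
    out = np.empty(len(peaks))
    for i, p in enumerate(peaks):
        iv = p.interval if hasattr(p, "interval") else p
        arr = arrs.get(iv.chrom)
        if arr is None or not len(arr):
            out[i] = np.inf
            continue
        idx = int(np.searchsorted(arr[:, 0], iv.end))
        best = np.inf
        if idx > 0:
            left = arr[idx - 1]
            best = 0.0 if left[1] > iv.start else iv.start - left[1]
        if idx < len(arr):
            right = arr[idx]
            d = 0.0 if right[0] < iv.end else right[0] - iv.end
            best = min(best, d)
        out[i] = best
    return out


def compare_distance_sets(dist_a, dist_b) -> tuple[float, float, float]:
    """Medians of both samples and a two-sided Mann-Whitney p.

    Exact enumeration when both n <= 8 and there are no ties, otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(np.median(a)), float(np.median(b)), float(res.pvalue)


def foldchange_bins(peak_ids, log2fc, covariate,
                    n_bins: int = 10) -> tuple[list[FoldChangeBin], float, float]:
    """Equal-occupancy fold-change bins and the across-bin Pearson correlation.

    Peaks are sorted by log2FC (ties broken by a stable sort on peak id) and
    cut into ``n_bins`` bins whose occupancies differ by at most 1. Returns
    (bins, r, p) of (median log2FC, median covariate) across bins.
    """
    peak_ids = list(peak_ids)
    log2fc = np.asarray(log2fc, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if len(peak_ids) < n_bins:
        raise ValidationError("fewer peaks than bins")
    if np.ptp(log2fc) == 0:
        raise ValidationError("constant log2FC: degenerate binning")
    order = sorted(range(len(peak_ids)), key=lambda i: (log2fc[i], peak_ids[i]))
    chunks = np.array_split(np.asarray(order), n_bins)
    bins = []
    for bi, chunk in enumerate(chunks):
        bins.append(FoldChangeBin(
            index=bi,
            peak_ids=[peak_ids[i] for i in chunk],
            median_covariate=float(np.median(covariate[chunk])),
            median_log2fc=float(np.median(log2fc[chunk])),
        ))
    xs = np.array([b.median_log2fc for b in bins])
    ys = np.array([b.median_covariate for b in bins])
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValidationError("degenerate bin medians: correlation undefined")
    r, p = stats.pearsonr(xs, ys)
    return bins, float(r), float(p)


# ---------------------------------------------------------------------------
# Repli-seq phase assignment
# ---------------------------------------------------------------------------

def repliseq_phase_assignment(peaks,
                              phase_tracks: dict[str, dict[str, BinnedTrack]],
                              phases: tuple[str, ...] = REPLI_PHASES,
                              ) -> tuple[pd.Series, int]:
    """Assign each peak the phase with the highest mean signal over the peak.

    Ties break toward the earlier phase in ``phases``. Peaks with all-zero
    phase signal are unassigned (NaN) and counted. Tracks must already be
    depth-normalized.
    """
    ids, calls = [], []
    n_unassigned = 0
    for i, p in enumerate(peaks):
        iv = p.interval if hasattr(p, "interval") else p
        means = np.zeros(len(phases))
        for k, ph in enumerate(phases):
            tr = phase_tracks[ph].get(iv.chrom)
            if tr is None:
                continue
            lo, hi = tr.bin_range(iv.start, iv.end)
            if hi > lo:
                means[k] = float(tr.values[lo:hi].mean())
        ids.append(getattr(p, "id", "") or f"peak_{i:06d}")
        if means.max() <= 0:
            calls.append(None)
            n_unassigned += 1
        else:
            calls.append(phases[int(np.argmax(means))])
    return pd.Series(calls, index=ids, name="phase"), n_unassigned


def phase_distribution_mc(matched: MatchedControlSet,
                          phase_tracks: dict[str, dict[str, BinnedTrack]],
                          n_mc: int = 249, seed: int = 0,
                          phases: tuple[str, ...] = REPLI_PHASES) -> pd.DataFrame:
    """Per-phase observed fraction of targets vs matched-control expectation.

    Uses the same Monte-Carlo machinery as overlap enrichment, one phase at a
    time (indicator statistic: peak assigned to that phase).
    """
    tids = sorted(matched.targets)
    t_calls, _ = repliseq_phase_assignment(
        [matched.targets[t].peak for t in tids], phase_tracks, phases)
    n_matches = min(len(matched.controls[t]) for t in tids)
    ctrl_calls = []
    for t in tids:
        calls, _ = repliseq_phase_assignment(
            [c.peak for c in matched.controls[t][:n_matches]],
            phase_tracks, phases)
        ctrl_calls.append(calls.values)
    ctrl_mat = np.array(ctrl_calls, dtype=object)
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, n_matches, size=(n_mc, len(tids)))
    rows = []
    for ph in phases:
        obs = float(np.mean(t_calls.values == ph))
        hit = (ctrl_mat == ph).astype(float)
        draws = hit[np.arange(len(tids))[None, :], picks].mean(axis=1)
        p_enr = (1 + int((draws >= obs).sum())) / (1 + n_mc)
        p_dep = (1 + int((draws <= obs).sum())) / (1 + n_mc)
        rows.append({"phase": ph, "observed": obs,
                     "expected": float(draws.mean()),
                     "p_value": min(1.0, 2 * min(p_enr, p_dep))})
    return pd.DataFrame(rows).set_index("phase")
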