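"""Two-state HMM segmentation of binned strand-specific coverage into peaks.

A background/peak HMM with negative-binomial emissions is fitted per strand
per sample by Baum-Welch. Two decoders are provided: ``standard`` emits
maximal Viterbi peak-state runs, while ``high_sensitivity`` seeds peaks where
the posterior peak probability is high and extends them outward through bins
of moderate posterior, capturing low and trailing signal flanks. Masked bins
break the Markov chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from ._hmm_core import forward_backward, segments_from_mask, viterbi_path
from .core_io import BinnedTrack, GenomicInterval

__all__ = [
    "HmmParams",
    "Peak",
    "DegenerateFitError",
    "fit_hmm",
    "viterbi",
    "posterior",
    "decode_peaks",
    "union_peaks",
]

BACKGROUND, PEAK = 0, 1
_MIN_DISP = 1e-8


class DegenerateFitError(RuntimeError):
    """Raised when EM cannot separate two emission states."""


@dataclass
class HmmParams:
    """Parameters of the 2-state background/peak chain.

    State 0 is background, state 1 is peak; the states are identifiable by
    the ordering ``means[1] > means[0]``. Emissions are negative binomial on
    integer bin counts (``family='nb'``) or Gaussian on log1p-transformed
    values (``family='gaussian_log1p'``).
    """

    pi: np.ndarray
    transitions: np.ndarray
    means: np.ndarray
    dispersions: np.ndarray
    family: str = "nb"
    converged: bool = True
    log_likelihood: float = float("nan")

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.dispersions = np.asarray(self.dispersions, dtype=float)
        if not np.allclose(self.pi.sum(), 1.0):
            raise ValueError("initial probabilities must sum to 1")
        if not np.allclose(self.transitions.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")

    def emission_loglik(self, x: np.ndarray) -> np.ndarray:
        """(T, 2) per-state log-likelihoods of observations."""
        x = np.asarray(x, dtype=float)
        out = np.empty((len(x), 2))
        for k in range(2):
            out[:, k] = _nb_logpmf(np.rint(x), self.means[k], self.dispersions[k]) \
                if self.family == "nb" else _gauss_loglik(
                    np.log1p(x), self.means[k], self.dispersions[k])
        return out


def _nb_logpmf(x, mean, disp):
    mean = max(float(mean), 1e-12)
    if disp < _MIN_DISP:
        return stats.poisson.logpmf(x, mean)
    r = 1.0 / disp
    p = r / (r + mean)
    return stats.nbinom.logpmf(x, r, p)


def _gauss_loglik(x, mean, sd):
    sd = max(float(sd), 1e-6)
    return stats.norm.logpdf(x, loc=mean, scale=sd)


def _gather_segments(tracks) -> list[np.ndarray]:
    if isinstance(tracks, BinnedTrack):
        tracks = [tracks]
    segs: list[np.ndarray] = []
    for tr in tracks:
        for lo, hi in segments_from_mask(tr.mask):
            segs.append(tr.values[lo:hi])
    return segs


def fit_hmm(tracks, max_iter: int = 50, tol: float = 1e-5,
            family: str = "nb") -> HmmParams:
    """Baum-Welch fit of the 2-state chain on one or more tracks.

    Chains restart at every masked gap and chromosome boundary, so the fit is
    invariant to chromosome concatenation order. Log-likelihood is
    non-decreasing (generalized EM: the dispersion update maximizes the
    expected log-likelihood numerically). States are relabeled at the end so
    the peak state has the larger mean.
    """
    segs = _gather_segments(tracks)
    n_total = sum(len(s) for s in segs)
    if n_total < 100:
        raise ValueError(f"need >= 100 unmasked bins to fit, got {n_total}")
    allx = np.concatenate(segs)
    if family == "nb":
        allx = np.rint(allx)
    else:
        allx = np.log1p(allx)
    if np.ptp(allx) == 0:
        raise DegenerateFitError("constant track: emission states collapse")

    lo_cut = np.quantile(allx, 0.90)
    bg0 = float(np.mean(allx[allx <= lo_cut]))
    top = allx[allx >= np.quantile(allx, 0.98)]
    pk0 = float(np.mean(top))
    if pk0 <= bg0 * 1.5 + 0.5:
        pk0 = bg0 * 2.0 + 1.0
    params = HmmParams(
        pi=np.array([0.95, 0.05]),
        transitions=np.array([[0.995, 0.005], [0.02, 0.98]]),
        means=np.array([max(bg0, 1e-3), pk0]),
        dispersions=np.array([0.2, 0.2]),
        family=family,
    )

    prev_ll = -np.inf
    log_floor = 1e-12
    for it in range(max_iter):
        pi_acc = np.zeros(2)
        xi_acc = np.zeros((2, 2))
        gsum = np.zeros(2)
        gxsum = np.zeros(2)
        ll_total = 0.0
        resp: list[np.ndarray] = []
        log_pi = np.log(params.pi + log_floor)
        log_a = np.log(params.transitions + log_floor)
        for seg in segs:
            loglik = params.emission_loglik(seg)
            gamma, xi, ll = forward_backward(log_pi, log_a, loglik)
            ll_total += ll
            pi_acc += gamma[0]
            xi_acc += xi
            x = np.rint(seg) if family == "nb" else np.log1p(seg)
            gsum += gamma.sum(axis=0)
            gxsum += gamma.T @ x
            resp.append(gamma)

        params.pi = pi_acc / pi_acc.sum()
        rows = xi_acc.sum(axis=1, keepdims=True)
        params.transitions = np.where(rows > 0, xi_acc / np.maximum(rows, 1e-300),
                                      params.transitions)
        params.transitions /= params.transitions.sum(axis=1, keepdims=True)
        new_means = gxsum / np.maximum(gsum, 1e-300)
        params.means = np.maximum(new_means, 1e-6)

        if family == "nb":
            for k in range(2):
                params.dispersions[k] = _mle_dispersion(
                    segs, resp, k, params.means[k])
        else:
            gx2 = np.zeros(2)
            for seg, gamma in zip(segs, resp):
                x = np.log1p(seg)
                for k in range(2):
                    gx2[k] += gamma[:, k] @ (x - params.means[k]) ** 2
            params.dispersions = np.sqrt(gx2 / np.maximum(gsum, 1e-300))

        if np.isfinite(prev_ll) and abs(ll_total - prev_ll) < tol * (abs(prev_ll) + 1.0):
            params.converged = True
            params.log_likelihood = ll_total
            break
        prev_ll = ll_total
        params.log_likelihood = ll_total
    else:
        params.converged = False
        warnings.warn("EM did not converge; returning best-so-far parameters")

    if params.means[PEAK] < params.means[BACKGROUND]:
        order = [PEAK, BACKGROUND]
        params.pi = params.pi[order]
        params.transitions = params.transitions[np.ix_(order, order)]
        params.means = params.means[order]
        params.dispersions = params.dispersions[order]
    if params.means[PEAK] <= params.means[BACKGROUND] * 1.02:
        warnings.warn("degenerate fit: state means nearly collapsed")
    return params


def _mle_dispersion(segs, resp, k, mean):
    """Maximize the state's expected NB log-likelihood over the dispersion."""
    xs = np.concatenate([np.rint(s) for s in segs])
    ws = np.concatenate([g[:, k] for g in resp])
    keep = ws > 1e-8
    xs, ws = xs[keep], ws[keep]
    if len(xs) == 0:
        return 0.1

    def neg(log_disp):
        return -float(ws @ _nb_logpmf(xs, mean, np.exp(log_disp)))

    res = minimize_scalar(neg, bounds=(np.log(1e-6), np.log(10.0)),
                          method="bounded", options={"xatol": 1e-3})
    return float(np.exp(res.x))


def viterbi(params: HmmParams, observations) -> np.ndarray:
    """Most probable state path for one unbroken observation segment."""
    observations = np.asarray(observations, dtype=float)
    if len(observations) == 0:
        return np.empty(0, dtype=np.int64)
    return viterbi_path(
        np.log(params.pi + 1e-300), np.log(params.transitions + 1e-300),
        params.emission_loglik(observations),
    )


def posterior(params: HmmParams, observations) -> np.ndarray:
    """(T, 2) posterior state probabilities for one unbroken segment."""
    observations = np.asarray(observations, dtype=float)
    if len(observations) == 0:
        return np.empty((0, 2))
    gamma, _, _ = forward_backward(
        np.log(params.pi + 1e-300), np.log(params.transitions + 1e-300),
        params.emission_loglik(observations),
    )
    return gamma


@dataclass(frozen=True)
class Peak:
    """A called peak: a stranded interval with decoding summaries."""

    interval: GenomicInterval
    sample: str = ""
    mean_posterior: float = 1.0
    mean_signal: float = 0.0
    samples: tuple = field(default_factory=tuple)
    id: str = ""

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


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    return segments_from_mask(~flags)


def decode_peaks(params: HmmParams, track: BinnedTrack, mode: str = "standard",
                 p_core: float = 0.9, p_tail: float = 0.5,
                 merge_gap: int = 500, min_peak_length: int = 300,
                 sample: str = "", normalized_values: np.ndarray | None = None,
                 ) -> list[Peak]:
    """Decode a fitted chain into peaks.

    ``standard``: maximal runs of Viterbi peak-state bins. ``high_sensitivity``:
    bins with chain-posterior peak probability >= p_core (or called peak by
    Viterbi) seed peaks, which then extend outward through contiguous bins
    that look like trailing signal. Trailing signal is modeled by an implicit
    emission state whose mean is the geometric mean of the background and
    peak means (background dispersion): a bin extends the peak while
    P(trail) / (P(trail) + P(background)) >= p_tail on emissions alone. The
    chain posterior collapses to the Viterbi boundary within a bin or two,
    so the extension deliberately ignores the transition prior — that is
    what lets low, decaying flanks join the peak, and it makes peak extent
    monotone in p_tail. Every standard-mode peak is contained in a
    high-sensitivity peak. Runs closer than ``merge_gap`` bp are merged
    within each unmasked segment; runs shorter than ``min_peak_length`` bp
    are dropped.
    """
    if mode not in ("standard", "high_sensitivity"):
        raise ValueError(f"unknown decoding mode {mode!r}")
    bw = track.bin_width
    sig = track.values if normalized_values is None else normalized_values
    peaks: list[Peak] = []
    for lo, hi in segments_from_mask(track.mask):
        seg = track.values[lo:hi]
        gamma = posterior(params, seg)
        post1 = gamma[:, 1]
        vit = viterbi(params, seg)
        if mode == "standard":
            flags = vit == PEAK
        else:
            seeds = (post1 >= p_core) | (vit == PEAK)
            trail_mean = float(np.sqrt(params.means[0] * params.means[1]))
            x = np.rint(seg) if params.family == "nb" else np.log1p(seg)
            if params.family == "nb":
                ll_trail = _nb_logpmf(x, trail_mean, params.dispersions[0])
                ll_bg = _nb_logpmf(x, params.means[0], params.dispersions[0])
            else:
                ll_trail = _gauss_loglik(x, np.log1p(trail_mean),
                                         params.dispersions[0])
                ll_bg = _gauss_loglik(x, params.means[0], params.dispersions[0])
            with np.errstate(over="ignore"):
                trail_post = 1.0 / (1.0 + np.exp(ll_bg - ll_trail))
            flags = (trail_post >= p_tail) | seeds
        runs = _runs(flags)
        # merge nearby runs (gap measured in bp, within this unmasked
        # segment), then keep only merged runs anchored by a seed
        merged: list[list[int]] = []
        for a, b in runs:
            if merged and (a - merged[-1][1]) * bw <= merge_gap:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        if mode == "high_sensitivity":
            merged = [r for r in merged if seeds[r[0]:r[1]].any()]
        for a, b in merged:
            start = (lo + a) * bw
            end = min((lo + b) * bw, track.chrom_length)
            if end - start < min_peak_length:
                continue
            peaks.append(Peak(
                interval=GenomicInterval(track.chrom, start, end, track.strand),
                sample=sample,
                mean_posterior=float(post1[a:b].mean()),
                mean_signal=float(np.asarray(sig[lo + a:lo + b]).mean()),
            ))
    return peaks


def union_peaks(per_sample_peaks: list[list[Peak]]) -> list[Peak]:
    """Per-strand interval union of peaks present in at least one sample.

    Overlapping or abutting intervals merge; each union peak records the set
    of contributing samples and gets a stable sequential id.
    """
    by_key: dict[tuple[str, str], list[Peak]] = {}
    for plist in per_sample_peaks:
        for p in plist:
            by_key.setdefault((p.chrom, p.strand), []).append(p)
    out: list[Peak] = []
    for (chrom, strand) in sorted(by_key):
        plist = sorted(by_key[(chrom, strand)], key=lambda p: (p.start, p.end))
        cur_s, cur_e = plist[0].start, plist[0].end
        cur_samples = {plist[0].sample}
        posts, sigs = [plist[0].mean_posterior], [plist[0].mean_signal]
        for p in plist[1:]:
            if p.start <= cur_e:
                cur_e = max(cur_e, p.end)
                cur_samples.add(p.sample)
                posts.append(p.mean_posterior)
                sigs.append(p.mean_signal)
            else:
                out.append(Peak(GenomicInterval(chrom, cur_s, cur_e, strand),
                                sample="union",
                                mean_posterior=float(np.mean(posts)),
                                mean_signal=float(np.mean(sigs)),
                                samples=tuple(sorted(cur_samples))))
                cur_s, cur_e = p.start, p.end
                cur_samples = {p.sample}
                posts, sigs = [p.mean_posterior], [p.mean_signal]
        out.append(Peak(GenomicInterval(chrom, cur_s, cur_e, strand),
                        sample="union", mean_posterior=float(np.mean(posts)),
                        mean_signal=float(np.mean(sigs)),
                        samples=tuple(sorted(cur_samples))))
    out.sort(key=lambda p: (p.chrom, p.start, p.end, p.strand))
    return [
        Peak(p.interval, p.sample, p.mean_posterior, p.mean_signal, p.samples,
             id=f"peak_{i:06d}")
        for i, p in enumerate(out)
    ]
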