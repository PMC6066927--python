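"""Replication fork directionality (RFD) computation and HMM segmentation.

RFD = (C - W) / (C + W) from Okazaki-fragment strand counts, binned at 1 kb
by default. The bin-to-bin RFD increments are segmented by a 3-state HMM
(flat, ascending, descending) with fixed-mean Gaussian emissions; ascending
runs are emitted as replication initiation zones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._hmm_core import segments_from_mask, viterbi_path
from .core_io import FeatureSet, GenomicInterval, ValidationError

__all__ = [
    "RFDProfile",
    "InitiationZone",
    "RfdHmmConfig",
    "compute_rfd",
    "segment_rfd",
    "initiation_zones_featureset",
]

FLAT, ASC, DESC = 0, 1, 2
STATE_NAMES = {FLAT: "flat", ASC: "AS", DESC: "DS"}


@dataclass
class RFDProfile:
    """Per-bin replication fork directionality in [-1, 1], NaN where undefined."""

    chrom: str
    bin_width: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[~np.isnan(self.values)]
        if len(finite) and (finite.min() < -1 or finite.max() > 1):
            raise ValidationError("RFD values must lie in [-1, 1]")

    def mirrored(self) -> "RFDProfile":
        """Sign-flipped profile (fork directions reversed)."""
        return RFDProfile(self.chrom, self.bin_width, -self.values)


@dataclass(frozen=True)
class InitiationZone:
    """An ascending-RFD segment: a replication initiation zone."""

    interval: GenomicInterval
    delta_rfd: float  # rfd at zone end minus rfd at zone start; > 0


@dataclass
class RfdHmmConfig:
    """Segmentation parameters.

    Emission means are fixed at (+drift, -drift, 0) for the AS/DS/flat
    states; only the shared Gaussian variance is fitted (a few EM sweeps).
    ``drift`` is the per-bin RFD increment expected inside a ramp; when None
    it is set to the 90th percentile of the absolute smoothed increments, a
    robust stand-in for the ramp slope. The profile is smoothed with a
    centered ``smooth_bins``-wide moving average before differencing (binned
    strand-count ratios are far noisier than the underlying slope).
    """

    drift: float | None = None
    stay_prob: float = 0.99
    min_zone_bins: int = 5
    smooth_bins: int = 5
    em_iterations: int = 5
    initial_sigma: float | None = None


def compute_rfd(crick: np.ndarray, watson: np.ndarray, chrom: str,
                bin_width: int = 1000, min_count: int = 10) -> RFDProfile:
    """RFD = (C - W)/(C + W) per bin; NaN where C + W < min_count."""
    c = np.asarray(crick, dtype=float)
    w = np.asarray(watson, dtype=float)
    if (c < 0).any() or (w < 0).any():
        raise ValidationError("strand counts must be non-negative")
    total = c + w
    with np.errstate(divide="ignore", invalid="ignore"):
        rfd = np.where(total >= min_count, (c - w) / np.maximum(total, 1e-300),
                       np.nan)
    return RFDProfile(chrom, bin_width, rfd)


def _transition_matrix(stay: float) -> np.ndarray:
    move = (1.0 - stay) / 2.0
    return np.array([
        [stay, move, move],
        [move, stay, move],
        [move, move, stay],
    ])


def segment_rfd(profile: RFDProfile, config: RfdHmmConfig | None = None):
    """Segment an RFD profile into flat/ascending/descending runs.

    Observations are the increments between consecutive defined bins; NaN
    bins break the chain. Returns (segments, zones): segments are
    (start_bin, end_bin, label) over bin index space, zones are the
    ascending runs of at least ``min_zone_bins`` bins as InitiationZones.
    Viterbi ties break toward flat. The construction is antisymmetric: on
    the sign-flipped profile the AS and DS segment sets swap exactly.
    """
    config = config or RfdHmmConfig()
    rfd = profile.values
    defined = ~np.isnan(rfd)
    if defined.sum() < 100:
        raise ValidationError("need >= 100 defined RFD bins")
    if np.nanstd(rfd) == 0:
        warnings.warn("constant RFD profile: no zones")
        return [], []

    chains = []
    for lo, hi in segments_from_mask(~defined):
        if hi - lo < 2:
            continue
        smooth = _moving_average(rfd[lo:hi], config.smooth_bins)
        chains.append((lo, np.diff(smooth)))
    if not chains:
        return [], []

    drift = config.drift
    if drift is None:
        alld0 = np.abs(np.concatenate([d for _, d in chains]))
        drift = max(float(np.quantile(alld0, 0.90)), 1e-6)
    means = np.array([0.0, drift, -drift])
    log_pi = np.log(np.full(3, 1.0 / 3.0))
    log_a = np.log(_transition_matrix(config.stay_prob))

    alld = np.concatenate([d for _, d in chains])
    sigma = config.initial_sigma or max(float(np.std(alld)), 1e-6)
    # fit the shared variance by EM with means and transitions held fixed
    from ._hmm_core import forward_backward

    for _ in range(config.em_iterations):
        num = 0.0
        den = 0.0
        for _, d in chains:
            ll = _gauss_loglik_matrix(d, means, sigma)
            gamma, _, _ = forward_backward(log_pi, log_a, ll)
            num += float((gamma * (d[:, None] - means[None, :]) ** 2).sum())
            den += float(gamma.sum())
        new_sigma = max(np.sqrt(num / max(den, 1e-300)), 1e-6)
        if abs(new_sigma - sigma) < 1e-9:
            sigma = new_sigma
            break
        sigma = new_sigma

    segments: list[tuple[int, int, str]] = []
    zones: list[InitiationZone] = []
    for lo, d in chains:
        path = viterbi_path(log_pi, log_a, _gauss_loglik_matrix(d, means, sigma))
        # increment t describes the step bin t -> t+1; a run of increments
        # [t, u) labels bins (t, u]; the chain's first bin joins the first run
        # so runs partition the defined domain
        t = 0
        while t < len(path):
            u = t
            while u < len(path) and path[u] == path[t]:
                u += 1
            state = int(path[t])
            b0 = lo + t + (0 if t == 0 else 1)
            b1 = lo + u + 1
            segments.append((b0, b1, STATE_NAMES[state]))
            if state == ASC and (b1 - b0) >= config.min_zone_bins:
                delta = float(np.sum(d[t:u]))
                if delta > 0:
                    zones.append(InitiationZone(
                        GenomicInterval(profile.chrom, b0 * profile.bin_width,
                                        b1 * profile.bin_width),
                        delta))
            t = u
    return segments, zones


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; window <= 1 is the identity."""
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, x[0]), x, np.full(window - 1 - pad, x[-1])])
    return np.convolve(padded, kernel, mode="valid")


def _gauss_loglik_matrix(d: np.ndarray, means: np.ndarray, sigma: float) -> np.ndarray:
    z = (d[:, None] - means[None, :]) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * np.log(2 * np.pi)


def initiation_zones_featureset(zones_by_chrom: dict[str, list[InitiationZone]],
                                name: str = "OKseq_AS") -> FeatureSet:
    ivs = [z.interval for zl in zones_by_chrom.values() for z in zl]
    return FeatureSet(name, ivs).sorted()
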