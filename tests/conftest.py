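"""Shared fixtures: the default synthetic dataset and the fitted pipeline.

The expensive artifacts (coverage for all samples, per-sample HMM fits,
union peaks, differential calls) are session-scoped so the unit suite and
the acceptance suite share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from rloopshift import diff_rloop as dr
from rloopshift import peakcall_hmm as pk
from rloopshift.core_io import exclude_regions, normalize_sample_tracks
from rloopshift.synthetic_data import SimConfig, simulate_coverage, simulate_dataset

DATASET_SEED = 1


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SimConfig(seed=DATASET_SEED))


@pytest.fixture(scope="session")
def coverage(default_dataset):
    """{sample: {(chrom, strand): BinnedTrack}} raw counts, blacklist-masked."""
    ds = default_dataset
    samples, totals = {}, {}
    for cond in ("control", "depleted"):
        for rep in range(1, ds.config.n_replicates + 1):
            tracks, total = simulate_coverage(ds, cond, rep)
            tracks = {k: exclude_regions(v, ds.features["blacklist"])
                      for k, v in tracks.items()}
            samples[f"{cond}_{rep}"] = tracks
            totals[f"{cond}_{rep}"] = total
    return samples, totals


@pytest.fixture(scope="session")
def normalized_coverage(coverage):
    samples, totals = coverage
    return normalize_sample_tracks(samples, totals)


@pytest.fixture(scope="session")
def condition_tracks(normalized_coverage):
    """Replicate-averaged depth-normalized tracks per condition."""
    out = {}
    for cond in ("control", "depleted"):
        merged = {}
        reps = [s for s in normalized_coverage if s.startswith(cond)]
        for key in normalized_coverage[reps[0]]:
            t = normalized_coverage[reps[0]][key].copy()
            t.values = np.mean(
                [normalized_coverage[r][key].values for r in reps], axis=0)
            merged[key] = t
        out[cond] = merged
    return out


@pytest.fixture(scope="session")
def called_peaks(default_dataset, coverage):
    """Per-sample high-sensitivity peaks plus standard-mode calls for one sample."""
    ds = default_dataset
    samples, _ = coverage
    per_sample = {}
    standard = {}
    params_by_sample = {}
    for sample, tracks in samples.items():
        peaks = []
        std = []
        for strand in ("+", "-"):
            trs = [tracks[(c, strand)] for c in sorted(ds.chrom_sizes)]
            params = pk.fit_hmm(trs, max_iter=30)
            params_by_sample[(sample, strand)] = params
            for tr in trs:
                peaks.extend(pk.decode_peaks(params, tr, mode="high_sensitivity",
                                             sample=sample))
                std.extend(pk.decode_peaks(params, tr, mode="standard",
                                           sample=sample))
        per_sample[sample] = peaks
        standard[sample] = std
    return per_sample, standard, params_by_sample


@pytest.fixture(scope="session")
def union(called_peaks):
    per_sample, _, _ = called_peaks
    return pk.union_peaks(list(per_sample.values()))


@pytest.fixture(scope="session")
def count_matrix(default_dataset, coverage, union):
    ds = default_dataset
    samples, _ = coverage
    return dr.count_in_peaks(union, samples, ds.config.conditions())


@pytest.fixture(scope="session")
def diff_results(count_matrix):
    return dr.diff_test(count_matrix)


@pytest.fixture(scope="session")
def gene_classes(default_dataset, union, diff_results):
    ds = default_dataset
    return dr.classify_genes(diff_results, union, ds.genes)
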