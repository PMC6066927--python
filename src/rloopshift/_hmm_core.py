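"""Log-space forward-backward and Viterbi kernels shared by the segmentation modules.

All kernels take a (T, K) matrix of per-observation per-state log-likelihoods,
so emission families are decided by the callers. Viterbi ties are broken
toward the lowest state index, which callers exploit by putting the
conservative state first.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e300


@njit(cache=True)
def _forward(log_pi, log_a, loglik):
    T, K = loglik.shape
    alpha = np.empty((T, K))
    for k in range(K):
        alpha[0, k] = log_pi[k] + loglik[0, k]
    for t in range(1, T):
        for k in range(K):
            m = NEG_INF
            for j in range(K):
                v = alpha[t - 1, j] + log_a[j, k]
                if v > m:
                    m = v
            s = 0.0
            for j in range(K):
                s += np.exp(alpha[t - 1, j] + log_a[j, k] - m)
            alpha[t, k] = m + np.log(s) + loglik[t, k]
    m = NEG_INF
    for k in range(K):
        if alpha[T - 1, k] > m:
            m = alpha[T - 1, k]
    s = 0.0
    for k in range(K):
        s += np.exp(alpha[T - 1, k] - m)
    return alpha, m + np.log(s)


@njit(cache=True)
def _backward(log_a, loglik):
    T, K = loglik.shape
    beta = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        for k in range(K):
            m = NEG_INF
            for j in range(K):
                v = log_a[k, j] + loglik[t + 1, j] + beta[t + 1, j]
                if v > m:
                    m = v
            s = 0.0
            for j in range(K):
                s += np.exp(log_a[k, j] + loglik[t + 1, j] + beta[t + 1, j] - m)
            beta[t, k] = m + np.log(s)
    return beta


@njit(cache=True)
def _viterbi(log_pi, log_a, loglik):
    T, K = loglik.shape
    delta = np.empty((T, K))
    back = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_pi[k] + loglik[0, k]
    for t in range(1, T):
        for k in range(K):
            best = NEG_INF
            arg = 0
            for j in range(K):
                v = delta[t - 1, j] + log_a[j, k]
                if v > best:  # strict: ties go to the lowest predecessor index
                    best = v
                    arg = j
            delta[t, k] = best + loglik[t, k]
            back[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    best = NEG_INF
    arg = 0
    for k in range(K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def forward_backward(log_pi: np.ndarray, log_a: np.ndarray, loglik: np.ndarray):
    """Posterior state probabilities, expected transition counts and log-likelihood.

    Returns (gamma, xi_sum, loglik_total) where gamma is (T, K) with rows
    summing to 1 and xi_sum is the (K, K) matrix of expected transition counts.
    """
    loglik = np.ascontiguousarray(loglik, dtype=float)
    alpha, ll = _forward(log_pi, log_a, loglik)
    beta = _backward(log_a, loglik)
    log_gamma = alpha + beta - ll
    gamma = np.exp(log_gamma)
    gamma /= gamma.sum(axis=1, keepdims=True)

    T, K = loglik.shape
    xi_sum = np.zeros((K, K))
    if T > 1:
        # xi[t, j, k] = alpha[t, j] + a[j, k] + b[t+1, k] + beta[t+1, k] - ll
        for j in range(K):
            for k in range(K):
                log_xi = (
                    alpha[:-1, j] + log_a[j, k] + loglik[1:, k] + beta[1:, k] - ll
                )
                xi_sum[j, k] = np.exp(log_xi).sum()
    return gamma, xi_sum, float(ll)


def viterbi_path(log_pi: np.ndarray, log_a: np.ndarray, loglik: np.ndarray) -> np.ndarray:
    """Most probable state path; empty observations give an empty path."""
    if len(loglik) == 0:
        return np.empty(0, dtype=np.int64)
    loglik = np.ascontiguousarray(loglik, dtype=float)
    return _viterbi(
        np.asarray(log_pi, dtype=float), np.asarray(log_a, dtype=float), loglik
    )


def segments_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous [lo, hi) runs of unmasked bins; masked bins break the chain."""
    ok = ~np.asarray(mask, dtype=bool)
    if not ok.any():
        return []
    d = np.diff(ok.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if ok[0]:
        starts.insert(0, 0)
    if ok[-1]:
        ends.append(len(ok))
    return list(zip(starts, ends))
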