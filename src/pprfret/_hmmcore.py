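"""Scaled forward-backward and Viterbi kernels for the variational HMM.

The kernels take *subnormalized* parameters (exponentials of expected log
transition/initial probabilities from the variational posterior) plus a
(T, K) matrix of expected log emission densities. JIT-compiled with numba
when available; the pure-Python definitions are the reference fallback.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def forward_backward(tilde_pi, tilde_a, logb):
    """Scaled forward-backward.

    Returns (gamma (T,K), xi_sum (K,K), lnZ) where lnZ is the log normalizer
    of the chain under the subnormalized parameters.
    """
    T, K = logb.shape
    gamma = np.empty((T, K))
    xi_sum = np.zeros((K, K))
    btil = np.empty((T, K))
    shift = np.empty(T)
    for t in range(T):
        m = logb[t, 0]
        for k in range(1, K):
            if logb[t, k] > m:
                m = logb[t, k]
        shift[t] = m
        for k in range(K):
            btil[t, k] = np.exp(logb[t, k] - m)

    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = tilde_pi[k] * btil[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * tilde_a[j, k]
            alpha[t, k] = acc * btil[t, k]
            s += alpha[t, k]
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s

    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
        gamma[T - 1, k] = alpha[T - 1, k]
    for t in range(T - 2, -1, -1):
        for j in range(K):
            acc = 0.0
            for k in range(K):
                acc += tilde_a[j, k] * btil[t + 1, k] * beta[t + 1, k]
            beta[t, j] = acc / c[t + 1]
        gs = 0.0
        for k in range(K):
            gamma[t, k] = alpha[t, k] * beta[t, k]
            gs += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= gs
        # transition responsibilities t -> t+1
        for j in range(K):
            for k in range(K):
                xi_sum[j, k] += (
                    alpha[t, j]
                    * tilde_a[j, k]
                    * btil[t + 1, k]
                    * beta[t + 1, k]
                    / c[t + 1]
                )

    lnz = 0.0
    for t in range(T):
        lnz += np.log(c[t]) + shift[t]
    return gamma, xi_sum, lnz


@njit(cache=False)
def viterbi(tilde_pi, tilde_a, logb):
    """Most probable state path under the subnormalized parameters."""
    T, K = logb.shape
    loga = np.empty((K, K))
    logpi = np.empty(K)
    for j in range(K):
        logpi[j] = np.log(tilde_pi[j]) if tilde_pi[j] > 0 else -1e300
        for k in range(K):
            loga[j, k] = np.log(tilde_a[j, k]) if tilde_a[j, k] > 0 else -1e300
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = logpi[k] + logb[0, k]
    for t in range(1, T):
        for k in range(K):
            best = delta[t - 1, 0] + loga[0, k]
            arg = 0
            for j in range(1, K):
                v = delta[t - 1, j] + loga[j, k]
                if v > best:
                    best = v
                    arg = j
            delta[t, k] = best + logb[t, k]
            psi[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path
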