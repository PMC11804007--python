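"""Scaled forward/backward recursions, numba-jitted when available.

The recursions are the only genuinely sequential part of HMM inference;
everything else in the package is vectorised numpy.  A pure-python fallback
keeps the package importable if numba cannot compile.
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

        def deco(f):
            return f

        return deco


@njit(cache=True)
def forward_scaled(B, A, pi):
    """Scaled forward pass.

    B: (T, K) emission likelihoods; returns (alpha_hat, c) where
    alpha_hat[t] sums to 1 and log-likelihood = sum(log(c)).
    """
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    s = a.sum()
    c[0] = s
    alpha[0] = a / s
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        s = a.sum()
        c[t] = s
        alpha[t] = a / s
    return alpha, c


@njit(cache=True)
def backward_scaled(B, A, c):
    """Scaled backward pass matching :func:`forward_scaled`'s scaling."""
    T, K = B.shape
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


@njit(cache=True)
def sample_markov_chain(pi_cum, A_cum, u):
    """Draw a state path from cumulative initial/transition rows using
    pre-drawn uniforms ``u`` (length T)."""
    T = u.shape[0]
    states = np.empty(T, dtype=np.int64)
    s = np.searchsorted(pi_cum, u[0], side="right")
    states[0] = s
    for t in range(1, T):
        s = np.searchsorted(A_cum[s], u[t], side="right")
        states[t] = s
    return states
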