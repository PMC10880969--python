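"""Scaled forward/backward recursions, JIT-compiled when numba is available.

E is passed code-major (n_codes, n_states) so each column's emission row
is contiguous; the likelihood kernel keeps a single running vector to
stay allocation-free inside the long loop.
"""

from __future__ import annotations

import numpy as np


def _loglik_py(pi, T, E, codes):
    L = codes.shape[0]
    S = pi.shape[0]
    Tt = np.ascontiguousarray(T.T)  # contiguous inner products
    a = np.empty(S)
    b = np.empty(S)
    e = E[codes[0]]
    c = 0.0
    for s in range(S):
        a[s] = pi[s] * e[s]
        c += a[s]
    ll = np.log(c)
    for s in range(S):
        a[s] /= c
    for t in range(1, L):
        e = E[codes[t]]
        c = 0.0
        for j in range(S):
            acc = 0.0
            for i in range(S):
                acc += a[i] * Tt[j, i]
            acc *= e[j]
            b[j] = acc
            c += acc
        ll += np.log(c)
        inv = 1.0 / c
        for j in range(S):
            a[j] = b[j] * inv
    return ll


def _forward_py(pi, T, E, codes):
    L = codes.shape[0]
    S = pi.shape[0]
    Tt = np.ascontiguousarray(T.T)
    alpha = np.empty((L, S))
    scale = np.empty(L)
    e = E[codes[0]]
    c = 0.0
    for s in range(S):
        alpha[0, s] = pi[s] * e[s]
        c += alpha[0, s]
    scale[0] = c
    for s in range(S):
        alpha[0, s] /= c
    for t in range(1, L):
        e = E[codes[t]]
        c = 0.0
        for j in range(S):
            acc = 0.0
            for i in range(S):
                acc += alpha[t - 1, i] * Tt[j, i]
            acc *= e[j]
            alpha[t, j] = acc
            c += acc
        scale[t] = c
        inv = 1.0 / c
        for j in range(S):
            alpha[t, j] *= inv
    return alpha, scale


def _backward_post_py(T, E, codes, alpha, scale):
    L, S = alpha.shape
    gamma = np.empty((L, S))
    b = np.ones(S)
    nb = np.empty(S)
    for s in range(S):
        gamma[L - 1, s] = alpha[L - 1, s]
    for t in range(L - 2, -1, -1):
        e = E[codes[t + 1]]
        inv = 1.0 / scale[t + 1]
        tot = 0.0
        for i in range(S):
            acc = 0.0
            for j in range(S):
                acc += T[i, j] * e[j] * b[j]
            nb[i] = acc * inv
        for i in range(S):
            b[i] = nb[i]
            g = alpha[t, i] * b[i]
            gamma[t, i] = g
            tot += g
        inv_tot = 1.0 / tot
        for i in range(S):
            gamma[t, i] *= inv_tot
    return gamma


try:  # pragma: no cover - exercised when numba is installed
    import numba

    _jit = numba.njit(cache=True, fastmath=True)
    forward = _jit(_forward_py)
    backward_posterior = _jit(_backward_post_py)
    loglik = _jit(_loglik_py)
except Exception:  # pragma: no cover
    forward = _forward_py
    backward_posterior = _backward_post_py
    loglik = _loglik_py
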