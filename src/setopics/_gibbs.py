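"""Numba kernels for the collapsed Gibbs sampler.

The RNG is a self-contained xorshift64* stream carried in a 1-element uint64
array, so a fit is bit-identical for a given seed regardless of platform
RNG state.  Counts are int64; probabilities are accumulated as a cumulative
sum so each token draw is a single uniform.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_MULT = np.uint64(2685821657736338717)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True)
def _rand_uniform(state):
    s = state[0]
    s ^= s >> np.uint64(12)
    s = (s ^ (s << np.uint64(25))) & _MASK
    s ^= s >> np.uint64(27)
    state[0] = s
    return float((s * _MULT) >> np.uint64(11)) * _INV53


@njit(cache=True)
def seed_state(seed):
    # splitmix64 finalizer; never leaves the state at zero
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) & _MASK
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK
    z ^= z >> np.uint64(31)
    if z == np.uint64(0):
        z = np.uint64(0x9E3779B97F4A7C15)
    out = np.empty(1, dtype=np.uint64)
    out[0] = z
    return out


@njit(cache=True)
def init_assignments(doc, word, n_topics, n_docs, n_words, state):
    """Uniform random initial topic labels and the implied count tables."""
    n_tok = doc.shape[0]
    z = np.empty(n_tok, dtype=np.int64)
    n_dk = np.zeros((n_docs, n_topics), dtype=np.int64)
    n_kw = np.zeros((n_topics, n_words), dtype=np.int64)
    n_k = np.zeros(n_topics, dtype=np.int64)
    for t in range(n_tok):
        k = int(_rand_uniform(state) * n_topics)
        if k == n_topics:
            k -= 1
        z[t] = k
        n_dk[doc[t], k] += 1
        n_kw[k, word[t]] += 1
        n_k[k] += 1
    return z, n_dk, n_kw, n_k


@njit(cache=True)
def sweep(doc, word, z, n_dk, n_kw, n_k, alpha, beta, state):
    """One full Gibbs sweep over every token, in fixed token order."""
    n_tok = doc.shape[0]
    K = n_dk.shape[1]
    V = n_kw.shape[1]
    vbeta = V * beta
    cum = np.empty(K, dtype=np.float64)
    for t in range(n_tok):
        d = doc[t]
        w = word[t]
        k = z[t]
        n_dk[d, k] -= 1
        n_kw[k, w] -= 1
        n_k[k] -= 1
        total = 0.0
        for j in range(K):
            total += (
                (n_kw[j, w] + beta) / (n_k[j] + vbeta) * (n_dk[d, j] + alpha)
            )
            cum[j] = total
        u = _rand_uniform(state) * total
        k = 0
        while k < K - 1 and cum[k] < u:
            k += 1
        z[t] = k
        n_dk[d, k] += 1
        n_kw[k, w] += 1
        n_k[k] += 1
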