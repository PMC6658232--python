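"""Independent oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and plain
Python arithmetic — and shares no code with the implementation paths it
checks.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def naive_path_score(emission, transition, path) -> float:
    """Plain-Python unnormalized log score of one label path."""
    s = float(emission[0][path[0]])
    for i in range(1, len(path)):
        s += float(transition[path[i - 1]][path[i]])
        s += float(emission[i][path[i]])
    return s


def brute_force_partition(emission, transition) -> float:
    """Sum of exp(score) over all |Y|^L label paths."""
    L, Y = np.asarray(emission).shape
    return sum(
        math.exp(naive_path_score(emission, transition, path))
        for path in product(range(Y), repeat=L)
    )


def brute_force_best(emission, transition) -> tuple[float, tuple[int, ...]]:
    """(max path score, lexicographically-first argmax path)."""
    L, Y = np.asarray(emission).shape
    best_score, best_path = -math.inf, None
    for path in product(range(Y), repeat=L):
        s = naive_path_score(emission, transition, path)
        if s > best_score:
            best_score, best_path = s, path
    return best_score, best_path


def brute_force_marginals(emission, transition) -> np.ndarray:
    """Per-position label marginals by explicit enumeration."""
    L, Y = np.asarray(emission).shape
    z = brute_force_partition(emission, transition)
    marg = np.zeros((L, Y))
    for path in product(range(Y), repeat=L):
        p = math.exp(naive_path_score(emission, transition, path)) / z
        for i, y in enumerate(path):
            marg[i, y] += p
    return marg


def central_difference(fn, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of a scalar function of x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        hi = fn(x)
        flat[i] = orig - h
        lo = fn(x)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * h)
    return g


def rel_err(a: np.ndarray, b: np.ndarray) -> float:
    """Max elementwise relative error with an absolute floor."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    denom = np.maximum(np.abs(a) + np.abs(b), 1.0)
    return float(np.max(np.abs(a - b) / denom))


def wilcoxon_enumeration_p(diffs: np.ndarray) -> float:
    """Two-sided exact Wilcoxon p by explicit 2^n sign enumeration."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=np.float64)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    observed = float(ranks[d > 0].sum())
    n_le = n_ge = 0
    for signs in product([0, 1], repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if w <= observed + 1e-9:
            n_le += 1
        if w >= observed - 1e-9:
            n_ge += 1
    total = 2**n
    return min(1.0, 2.0 * min(n_le / total, n_ge / total))
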