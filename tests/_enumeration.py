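"""Exhaustive-enumeration oracle for the monotone-trajectory posterior.

Discretizes the density range into equal cells and sums the Gaussian
likelihood over every non-decreasing level sequence, weighting each
sequence by the fraction of its cell block that lies inside the monotone
cone (a run of r tied levels contributes 1/r!).  This is a midpoint
quadrature of the continuous flat-prior posterior, independent of the
Metropolis-Hastings implementation it cross-checks.
"""

from itertools import combinations_with_replacement
from math import factorial

import numpy as np


def enumerate_monotone_marginals(
    data: np.ndarray, sigma: float, n_levels: int, lo: float, hi: float
) -> np.ndarray:
    """Per-time marginal posterior over density levels, (n_times, n_levels)."""
    data = np.asarray(data, float)
    n = data.size
    h = (hi - lo) / n_levels
    mids = lo + (np.arange(n_levels) + 0.5) * h
    marg = np.zeros((n, n_levels))
    for levels in combinations_with_replacement(range(n_levels), n):
        x = mids[list(levels)]
        w = np.exp(-np.sum((x - data) ** 2) / (2.0 * sigma**2))
        run = 1
        for i in range(1, n):
            if levels[i] == levels[i - 1]:
                run += 1
            else:
                w /= factorial(run)
                run = 1
        w /= factorial(run)
        for t, lvl in enumerate(levels):
            marg[t, lvl] += w
    return marg / marg.sum(axis=1, keepdims=True)


def sample_marginals(
    samples: np.ndarray, n_levels: int, lo: float, hi: float
) -> np.ndarray:
    """Histogram MCMC samples onto the same level grid, (n_times, n_levels)."""
    h = (hi - lo) / n_levels
    out = np.zeros((samples.shape[1], n_levels))
    for t in range(samples.shape[1]):
        idx = np.clip(((samples[:, t] - lo) / h).astype(int), 0, n_levels - 1)
        out[t] = np.bincount(idx, minlength=n_levels) / samples.shape[0]
    return out


def total_variation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Per-time TV distance between two (n_times, n_levels) marginal sets."""
    return 0.5 * np.abs(p - q).sum(axis=1)
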