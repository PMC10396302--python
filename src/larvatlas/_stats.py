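"""Shared statistical primitives.

The work-horse is a vectorized two-sided Wilcoxon rank-sum (Mann-Whitney)
test applied gene-by-gene to two groups of cells: normal approximation with
tie correction and continuity correction, matching the exact permutation
statistic (checked against enumeration in the test suite for small groups).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata

LOG2FC_EPS = 1e-9


def mannwhitney_u(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    """Per-column Mann-Whitney U statistic for group A (ties counted 1/2).

    Inputs are (n_a x g) and (n_b x g); returns a length-g vector of
    U = (rank-sum of A) - n_a (n_a + 1) / 2.
    """
    x_a = np.atleast_2d(np.asarray(x_a, dtype=np.float64))
    x_b = np.atleast_2d(np.asarray(x_b, dtype=np.float64))
    n_a = x_a.shape[0]
    stacked = np.vstack([x_a, x_b])
    ranks = rankdata(stacked, axis=0, method="average")
    return ranks[:n_a].sum(axis=0) - n_a * (n_a + 1) / 2.0


def _tie_term(stacked: np.ndarray) -> np.ndarray:
    """Per-column sum of t^3 - t over groups of tied values."""
    n, g = stacked.shape
    s = np.sort(stacked, axis=0)
    new_run = np.ones((n, g), dtype=bool)
    new_run[1:] = s[1:] != s[:-1]
    run_id = np.cumsum(new_run, axis=0) - 1  # 0..n-1 within each column
    flat = run_id + np.arange(g)[None, :] * n
    counts = np.bincount(flat.ravel(), minlength=n * g).reshape(g, n)
    c = counts.astype(np.float64)
    return (c**3 - c).sum(axis=1)


def wilcoxon_rank_sum(
    x_a: np.ndarray, x_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided rank-sum test per column; returns (U, p).

    Normal approximation with tie correction and 0.5 continuity correction.
    Columns where every value is tied get p = 1.
    """
    x_a = np.atleast_2d(np.asarray(x_a, dtype=np.float64))
    x_b = np.atleast_2d(np.asarray(x_b, dtype=np.float64))
    n_a, n_b = x_a.shape[0], x_b.shape[0]
    n = n_a + n_b
    stacked = np.vstack([x_a, x_b])
    u = mannwhitney_u(x_a, x_b)
    mu = n_a * n_b / 2.0
    tie = _tie_term(stacked)
    var = n_a * n_b / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    diff = u - mu
    # continuity correction shrinks |diff| by 0.5
    adj = np.sign(diff) * np.maximum(np.abs(diff) - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, adj / np.where(sd > 0, sd, 1.0), 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    p = np.where(sd > 0, np.minimum(p, 1.0), 1.0)
    return u, p


def log2_fold_change(
    mean_a: np.ndarray, mean_b: np.ndarray, eps: float = LOG2FC_EPS
) -> np.ndarray:
    """log2((mean_a + eps) / (mean_b + eps)) with a small stabilizer."""
    return np.log2((np.asarray(mean_a) + eps) / (np.asarray(mean_b) + eps))


def bonferroni(p: np.ndarray) -> np.ndarray:
    return np.minimum(np.asarray(p) * len(np.atleast_1d(p)), 1.0)
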