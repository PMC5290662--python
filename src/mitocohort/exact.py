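"""Exact small-sample tests shared by the burden and copy-number analyses.

Two-sided Fisher p-values follow the point-probability rule (sum of
hypergeometric point masses no larger than the observed table's, conditional
on both margins) — the convention of R's ``fisher.test``. Mann-Whitney uses
full enumeration of group assignments when the smaller group has at most
``MWU_EXACT_MAX`` observations (tie-aware, via average ranks), and the normal
approximation with tie correction otherwise. Spearman p-values use exact
permutation enumeration for n <= ``SPEARMAN_EXACT_MAX`` and the
t-approximation otherwise.
"""

from __future__ import annotations

import warnings
from itertools import combinations, permutations

import numpy as np
from scipy import stats

# Relative gate when comparing floating point masses, as in R's fisher.test.
_PMF_GATE = 1 + 1e-7

MWU_EXACT_MAX = 8
SPEARMAN_EXACT_MAX = 9


class DegenerateTableWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def fisher_support_pvalues(total: int, row1: int, col1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided p-values for every table with the given margins.

    For margins (N, row-1 total r, column-1 total c) the top-left count a
    ranges over ``max(0, r + c - N) .. min(r, c)``. Returns (support, p)
    where ``p[i]`` is the two-sided point-probability p-value of the table
    with a = support[i]. One batch call per margin class makes genome-wide
    scans cheap.
    """
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, total, row1, col1)
    # p[i] = sum of masses not exceeding pmf[i] (with a relative float gate)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    sorted_pmf = pmf[order]
    idx = np.searchsorted(sorted_pmf, pmf * _PMF_GATE, side="right")
    p = csum[np.maximum(idx - 1, 0)]
    return support, np.minimum(p, 1.0)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p-value of a 2x2 count table.

    A table with a zero margin carries no information about association;
    by convention p = 1 is returned with a warning.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    total = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or row1 == total or col1 == 0 or col1 == total:
        warnings.warn("2x2 table has a zero margin; p = 1 by convention",
                      DegenerateTableWarning, stacklevel=2)
        return 1.0
    support, p = fisher_support_pvalues(total, row1, col1)
    return float(p[support == a][0])


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _u_statistic(ranks: np.ndarray, idx_x: np.ndarray, n1: int, n2: int) -> float:
    return float(ranks[idx_x].sum() - n1 * (n1 + 1) / 2)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U of the first sample, p).

    Exact by full enumeration of the C(n1+n2, n1) group assignments when
    min(n1, n2) <= 8 (ties handled through average ranks, i.e. a permutation
    test on U); otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks, np.arange(n1), n1, n2)
    mu = n1 * n2 / 2
    if min(n1, n2) <= MWU_EXACT_MAX:
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks, np.array(idx), n1, n2)
            if abs(u - mu) >= dev_obs - 1e-9:
                count += 1
            total += 1
        return u_obs, count / total
    # asymptotic with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    sigma2 = n1 * n2 / 12 * (n + 1 - tie_term / (n * (n - 1)))
    if sigma2 == 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)
    return u_obs, float(2 * stats.norm.sf(max(z, 0.0)))


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; returns (rho, p).

    Exact two-sided p by permutation enumeration for n <= 9, else the
    two-sided t-approximation. Constant input leaves rho undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("samples must have equal length")
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_MAX:
        perms = np.array(list(permutations(range(n))))
        permuted = ry[perms]  # (n!, n)
        rx_c = rx - rx.mean()
        py_c = permuted - permuted.mean(axis=1, keepdims=True)
        denom = np.sqrt((rx_c**2).sum() * (py_c**2).sum(axis=1))
        rhos = (py_c @ rx_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        return rho_obs, p
    if abs(rho_obs) >= 1.0:
        return rho_obs, 0.0
    t = rho_obs * np.sqrt((n - 2) / (1 - rho_obs**2))
    return rho_obs, float(2 * stats.t.sf(abs(t), n - 2))
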