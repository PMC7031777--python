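"""Statistical engine for rank-based and group-based enrichment testing.

This module houses the primitives every other stage leans on:

* the hypergeometric upper tail and the minimum-hypergeometric (mHG)
  statistic with an exact p-value computed by dynamic programming over the
  rank/member lattice — the rank-based enrichment test used to ask whether
  a gene set concentrates near the top of a ranked list;
* Welch's unequal-variance two-sample t-test and the one-sample t-test,
  with explicit handling of the degenerate zero-variance cases;
* Storey's q-value procedure for multiple-testing correction, with the
  proportion of true nulls (pi0) estimated on a lambda grid and a
  cubic-smoother extrapolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "hypergeometric_tail",
    "mhg_pvalue",
    "welch_t_test",
    "one_sample_t_test",
    "qvalues",
]


@dataclass
class EnrichmentResult:
    """Outcome of one enrichment test.

    Attributes
    ----------
    pvalue : float
        Significance of the test.
    statistic : float
        The raw test statistic (for mHG, the minimal hypergeometric tail).
    n_star : int
        Optimal prefix length achieving the mHG minimum (1..N).
    k_star : int
        Number of members inside the optimal prefix.
    background_size : int
        Size N of the ranked background.
    set_size : int
        Number K of members of the target set in the background.
    qvalue : float | None
        FDR-adjusted value, filled in when tests are batch-corrected.
    """

    pvalue: float
    statistic: float
    n_star: int
    k_star: int
    background_size: int
    set_size: int
    qvalue: float | None = None


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the population size, K the number of marked items, n the sample
    (prefix) size and k the observed count of marked items in the sample.
    Computed through the survival function in log-stable form.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _hgt_lattice(N: int, K: int) -> np.ndarray:
    """Matrix of HGT(N, K, n, k) for n = 0..N (rows) and k = 0..K (cols).

    Unreachable cells (k > n or k < n - (N - K)) are set to +inf so they
    never enter a minimum.
    """
    n_grid = np.arange(N + 1)[:, None]
    k_grid = np.arange(K + 1)[None, :]
    with np.errstate(all="ignore"):
        tail = stats.hypergeom.sf(k_grid - 1, N, K, n_grid)
    reachable = (k_grid <= n_grid) & (k_grid >= n_grid - (N - K))
    tail = np.where(reachable, tail, np.inf)
    return tail


def mhg_pvalue(membership, exact: bool | None = None) -> EnrichmentResult:
    """Minimum-hypergeometric enrichment of a binary membership ranking.

    Parameters
    ----------
    membership : sequence of {0, 1}
        The ranked list encoded as membership indicators, best rank first.
    exact : bool, optional
        Force (True) or suppress (False) the exact dynamic-programming
        p-value.  By default the exact computation is used up to
        N = 50 000; beyond that a conservative Bonferroni-style bound
        (statistic times the number of distinct prefixes) is reported.

    Returns
    -------
    EnrichmentResult
        The mHG statistic (minimal hypergeometric tail over all prefix
        lengths), the optimal prefix, and the p-value of observing a
        statistic at least as extreme under uniformly random orderings.

    Notes
    -----
    The exact p-value follows the lattice path-counting argument: a
    ranking of K members among N items is a monotone path from (0, 0) to
    (N, K); the p-value is one minus the probability that a uniformly
    random path avoids every cell (n, k) whose hypergeometric tail is at
    or below the observed statistic.  The recursion uses the conditional
    step probabilities of the hypergeometric walk, so the result is exact
    up to floating-point rounding.
    """
    member = np.asarray(membership, dtype=np.int64)
    if member.ndim != 1 or member.size < 1:
        raise ValueError("membership must be a non-empty 1-D binary vector")
    if not np.isin(member, (0, 1)).all():
        raise ValueError("membership entries must be 0 or 1")
    N = int(member.size)
    K = int(member.sum())
    if K == 0:
        warnings.warn("empty target set: mHG is degenerate, p = 1", stacklevel=2)
        return EnrichmentResult(1.0, 1.0, N, 0, N, 0)

    tail = _hgt_lattice(N, K)
    prefix_k = np.cumsum(member)
    path_tail = tail[np.arange(1, N + 1), prefix_k]
    i_min = int(np.argmin(path_tail))
    statistic = float(path_tail[i_min])
    n_star = i_min + 1
    k_star = int(prefix_k[i_min])

    if exact is None:
        exact = N <= 50_000
    if not exact:
        p = min(1.0, statistic * N)
        return EnrichmentResult(p, statistic, n_star, k_star, N, K)

    # Cells "at least as extreme" as the observed statistic, with a tiny
    # relative tolerance so the observed cell is always inside the region.
    extreme = tail <= statistic * (1.0 + 1e-12)

    # f[k] = P(random path reaches (n, k) without entering an extreme cell)
    f = np.zeros(K + 1)
    f[0] = 1.0
    if extreme[0, 0]:
        f[0] = 0.0
    for n in range(1, N + 1):
        remaining = N - n + 1  # items left before step n
        k_vals = np.arange(K + 1)
        p_member = np.clip((K - k_vals) / remaining, 0.0, 1.0)
        new = f * (1.0 - p_member)
        new[1:] += f[:-1] * p_member[:-1]
        new[extreme[n, :]] = 0.0
        f = new
    p_exact = min(1.0, max(float(1.0 - f[K]), statistic))
    return EnrichmentResult(p_exact, statistic, n_star, k_star, N, K)


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Two-sample t-test with unequal variances (Welch).

    Returns ``(t, df, p)`` with Satterthwaite degrees of freedom and a
    two-sided p-value.  Degenerate inputs where both samples have zero
    variance yield t=0, p=1 for equal means, and p=0 (with a warning) for
    different means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        warnings.warn(
            "zero variance in both samples with different means", stacklevel=2
        )
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return sign * np.inf, float(na + nb - 2), 0.0
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def one_sample_t_test(x, mu0: float = 0.0) -> tuple[float, float]:
    """One-sample t-test of mean(x) against mu0; returns (t, two-sided p)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0.0:
        if x[0] == mu0:
            return 0.0, 1.0
        warnings.warn("zero variance sample off target mean", stacklevel=2)
        return float(np.sign(x[0] - mu0)) * np.inf, 0.0
    t = (x.mean() - mu0) / (sd / np.sqrt(x.size))
    p = 2.0 * stats.t.sf(abs(t), x.size - 1)
    return float(t), float(p)


def estimate_pi0(pvals: np.ndarray) -> float:
    """Estimate the proportion of true nulls from a p-value batch.

    Uses the lambda-grid estimator pi0(lambda) = #{p > lambda} / (m (1 -
    lambda)) on lambda = 0.05, 0.10, ..., 0.95, smoothed with a cubic
    polynomial and evaluated at the largest lambda.  Falls back to 1 for
    small batches (m < 100), where the estimator is unstable.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m < 100:
        return 1.0
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > la).sum() / (m * (1.0 - la)) for la in lam])
    coef = np.polyfit(lam, pi0_lam, deg=3)
    pi0 = float(np.polyval(coef, lam[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def qvalues(pvals) -> np.ndarray:
    """Storey q-values for a batch of p-values.

    q_i = pi0 * m * p_(i) / i with step-up enforcement of monotonicity
    (each q is the minimum over itself and all larger p's q).  With
    pi0 = 1 this reduces to Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
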