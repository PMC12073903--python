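"""Native nonparametric primitives: Mann-Whitney U, Benjamini-Hochberg,
and the one-sample Kolmogorov-Smirnov statistic against Uniform(0,1).

These are implemented from their definitions rather than delegated, so
that exact small-sample modes, tie handling, and the enrichment-specific
KS variant are fully under this package's control. scipy is used only
for the normal survival function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "TestResult",
    "InputSizeError",
    "ValidationError",
    "mann_whitney_u",
    "benjamini_hochberg",
    "ks_uniform",
]


class InputSizeError(ValueError):
    """Raised when a sample is too small for the requested test."""


class ValidationError(ValueError):
    """Raised when inputs violate a numeric precondition (e.g. p outside [0,1])."""


@dataclass
class TestResult:
    """Outcome of a single hypothesis test on one compound or one set.

    ``q_value`` is NaN until a Benjamini-Hochberg pass fills it in.
    ``direction`` is "up"/"down"/"none" (sign of the location difference,
    treated minus control by argument convention).
    """

    statistic: float
    p_raw: float
    q_value: float = math.nan
    direction: str = "none"
    n_per_group: tuple[int, ...] = ()
    method: str = ""
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mwu_null_counts(m: int, n: int) -> list[int]:
    """Exact tie-free null counts of U over all C(m+n, m) arrangements.

    ``counts[u]`` is the number of interleavings of m x's and n y's with
    exactly u (x, y) pairs where x ranks above y. Classic recurrence on
    the largest pooled observation: if it is an x it dominates all n y's.
    """
    if m * n > 40_000:  # ~200x200; guards accidental huge exact calls
        raise InputSizeError("exact Mann-Whitney null too large; use asymptotic mode")
    f: list[list[list[int]]] = [[[1] for _ in range(n + 1)]]
    for i in range(1, m + 1):
        row: list[list[int]] = [[1]]
        for j in range(1, n + 1):
            a = f[i - 1][j]  # largest is an x: shift by j
            b = row[j - 1]  # largest is a y: no shift
            size = max(len(a) + j, len(b))
            out = [0] * size
            for u, c in enumerate(a):
                out[u + j] += c
            for u, c in enumerate(b):
                out[u] += c
            row.append(out)
        f.append(row)
    return f[m][n]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U_x = #{(i,j): x_i > y_j} with ties counted 1/2, via midranks."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def _tie_sizes(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts


def _two_sided_from_tails(p_lo: float, p_hi: float) -> float:
    return min(1.0, 2.0 * min(p_lo, p_hi))


def _enumerate_u_pvalue(x: np.ndarray, y: np.ndarray, u_obs: float,
                        alternative: str) -> float:
    """Exact p by enumerating which pooled observations fall in the x group.

    Used when ties are present, where the rank-count recurrence no longer
    applies; each of the C(n1+n2, n1) assignments is equally likely under
    the null of exchangeability.
    """
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    total = math.comb(n, n1)
    if total > 2_000_000:
        raise InputSizeError(
            f"exact enumeration over {total} assignments is infeasible; "
            "use asymptotic mode")
    lo = hi = 0
    idx = np.arange(n)
    for comb in combinations(idx, n1):
        mask = np.zeros(n, bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if u <= u_obs + 1e-12:
            lo += 1
        if u >= u_obs - 1e-12:
            hi += 1
    p_lo, p_hi = lo / total, hi / total
    if alternative == "less":
        return p_lo
    if alternative == "greater":
        return p_hi
    return _two_sided_from_tails(p_lo, p_hi)


def mann_whitney_u(x: Sequence[float], y: Sequence[float], mode: str = "auto",
                   alternative: str = "two-sided",
                   continuity: bool = True) -> TestResult:
    """Two-sample Mann-Whitney U test (x is the treated group by convention).

    Parameters
    ----------
    mode : {"exact", "asymptotic", "auto"}
        ``exact`` enumerates the null distribution (rank recurrence when
        tie-free, full assignment enumeration otherwise). ``asymptotic``
        uses the normal approximation with tie-corrected variance and,
        by default, a continuity correction. ``auto`` picks exact for
        tie-free pooled samples with n1+n2 <= 20.
    alternative : {"two-sided", "greater", "less"}
        ``greater`` means x tends to exceed y.

    Returns
    -------
    TestResult with ``statistic`` = U of x, direction from the sign of
    median(x) - median(y) (falling back to rank dominance when the median
    difference is exactly zero).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InputSizeError(f"need at least 2 observations per group, got {n1} and {n2}")
    pooled = np.concatenate([x, y])
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if np.all(pooled == pooled[0]):
        return TestResult(statistic=u, p_raw=1.0, direction="none",
                          n_per_group=(n1, n2), method="degenerate")

    ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (n1 + n2 <= 20 and not ties) else "asymptotic"

    if mode == "exact":
        if ties:
            p = _enumerate_u_pvalue(x, y, u, alternative)
            method = "exact-enumeration"
        else:
            counts = _mwu_null_counts(n1, n2)
            total = sum(counts)
            ui = int(round(u))
            p_lo = sum(counts[: ui + 1]) / total
            p_hi = sum(counts[ui:]) / total
            if alternative == "less":
                p = p_lo
            elif alternative == "greater":
                p = p_hi
            else:
                p = _two_sided_from_tails(p_lo, p_hi)
            method = "exact"
    elif mode == "asymptotic":
        n = n1 + n2
        tie_term = float(np.sum(_tie_sizes(pooled) ** 3 - _tie_sizes(pooled)))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        sigma = math.sqrt(max(sigma2, 0.0))
        if sigma == 0.0:
            return TestResult(statistic=u, p_raw=1.0, direction="none",
                              n_per_group=(n1, n2), method="degenerate")
        diff = u - mu
        cc = 0.5 if continuity else 0.0
        if alternative == "two-sided":
            z = (abs(diff) - cc) / sigma
            p = 2.0 * norm.sf(max(z, 0.0))
        elif alternative == "greater":
            z = (diff - cc) / sigma
            p = norm.sf(z)
        else:
            z = (diff + cc) / sigma
            p = norm.cdf(z)
        p = float(min(1.0, p))
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    med_diff = float(np.median(x) - np.median(y))
    if med_diff > 0:
        direction = "up"
    elif med_diff < 0:
        direction = "down"
    elif u != mu:
        direction = "up" if u > mu else "down"
    else:
        direction = "none"
    return TestResult(statistic=u, p_raw=float(p), direction=direction,
                      n_per_group=(n1, n2), method=method)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped to 1, where m counts the
    non-missing p-values. NaNs are excluded from the family and returned
    as NaN in place.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    ps = p[mask]
    if ps.size and (ps.min() < 0 or ps.max() > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    out[mask] = q
    return out


# ---------------------------------------------------------------------------
# One-sample Kolmogorov-Smirnov against Uniform(0,1)
# ---------------------------------------------------------------------------

def _ks_cdf_exact(n: int, d: float) -> float:
    """P(D_n < d) by the Marsaglia-Tsang-Wang matrix method (exact, n <= ~100)."""
    if d <= 0:
        return 0.0
    if d >= 1:
        return 1.0
    k = int(math.ceil(n * d))
    h = k - n * d
    m = 2 * k - 1
    ij = np.subtract.outer(np.arange(m), np.arange(m)) + 1  # i - j + 1
    H = (ij >= 0).astype(float)
    hp = h ** np.arange(1, m + 1)
    H[:, 0] -= hp
    H[m - 1, :] -= hp[::-1]
    if 2 * h - 1 > 0:
        H[m - 1, 0] += (2 * h - 1) ** m
    fact = np.ones(m + 2)
    fact[1:] = np.cumprod(np.arange(1, m + 2, dtype=float))
    H[ij > 0] /= fact[ij[ij > 0]]
    # H^n with power-of-two scaling to avoid overflow
    eQ = 0
    Q = H.copy()
    power = n
    # binary exponentiation with rescaling
    result = np.eye(m)
    eR = 0
    while power:
        if power & 1:
            result = result @ Q
            eR += eQ
            if result.max() > 1e140:
                result *= 1e-140
                eR += 140
        power >>= 1
        if power:
            Q = Q @ Q
            eQ *= 2
            if Q.max() > 1e140:
                Q *= 1e-140
                eQ += 140
    s = result[k - 1, k - 1]
    for i in range(1, n + 1):
        s *= i / n
        if s < 1e-140:
            s *= 1e140
            eR -= 140
    return float(min(max(s * 10.0 ** eR, 0.0), 1.0))


def _kolmogorov_sf(x: float) -> float:
    """Survival function of the Kolmogorov distribution."""
    if x <= 0:
        return 1.0
    total = 0.0
    for kk in range(1, 101):
        term = 2.0 * (-1.0) ** (kk - 1) * math.exp(-2.0 * kk * kk * x * x)
        total += term
        if abs(term) < 1e-12:
            break
    return float(min(max(total, 0.0), 1.0))


def ks_uniform(p_set: Sequence[float], mode: str = "auto") -> TestResult:
    """One-sample KS test of a p-value set against Uniform(0,1).

    This is the set statistic used by chemical-class enrichment: a class
    whose member p-values pile up near zero departs from uniformity.

    ``mode`` is "exact" (Marsaglia-Tsang-Wang, default for n <= 50),
    "asymptotic" (Kolmogorov limit with the Stephens small-sample
    effective-n correction), or "auto".
    """
    u = np.asarray(p_set, float)
    u = u[~np.isnan(u)]
    n = len(u)
    if n < 2:
        raise InputSizeError("KS uniformity test needs at least 2 p-values")
    if u.min() < 0 or u.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    u = np.sort(u)
    i = np.arange(1, n + 1)
    d_plus = float(np.max(i / n - u))
    d_minus = float(np.max(u - (i - 1) / n))
    d = max(d_plus, d_minus)
    if mode == "auto":
        mode = "exact" if n <= 50 else "asymptotic"
    if mode == "exact":
        p = 1.0 - _ks_cdf_exact(n, d)
        method = "exact"
    elif mode == "asymptotic":
        eff = math.sqrt(n) + 0.12 + 0.11 / math.sqrt(n)
        p = _kolmogorov_sf(eff * d)
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(statistic=d, p_raw=float(min(max(p, 0.0), 1.0)),
                      direction="none", n_per_group=(n,), method=method)
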