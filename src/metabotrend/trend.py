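"""Jonckheere-Terpstra test for monotone trend across ordered groups.

The statistic is J = sum over ordered group pairs (i < j) of the
Mann-Whitney count of pairs (a in group i, b in group j) with b > a,
ties counted 1/2. Groups are ordered a priori by the lifespan-extension
effect of the intervention; only the ordering enters the statistic.

Exact null distributions (tie-free) are computed by Harding's
decomposition: under exchangeability J is the sum of independent
Mann-Whitney statistics of each group against the union of the groups
before it, so the null counts are a convolution of Mann-Whitney null
counts. This is arithmetically identical to enumerating every distinct
assignment of observations to groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .stats_core import InputSizeError, _mwu_null_counts, benjamini_hochberg
from . import design

__all__ = [
    "DesignError",
    "OrderedDesign",
    "TrendResult",
    "jonckheere",
    "trend_scan",
]

log = logging.getLogger(__name__)


class DesignError(ValueError):
    """Raised when the group structure cannot support a trend test."""


@dataclass(frozen=True)
class GroupSpec:
    label: str
    lifespan_pct: float
    sample_ids: tuple[str, ...]


@dataclass(frozen=True)
class OrderedDesign:
    """Per-sex, per-organ ordered treatment groups for trend testing."""

    groups: tuple[GroupSpec, ...]
    sex: str
    organ: str

    def __post_init__(self) -> None:
        pcts = [g.lifespan_pct for g in self.groups]
        if any(b < a for a, b in zip(pcts, pcts[1:])):
            raise DesignError("lifespan percentages must be non-decreasing along the order")
        if len(self.groups) < 3:
            raise DesignError("trend testing needs at least 3 ordered groups")

    @classmethod
    def from_metadata(cls, metadata: pd.DataFrame, sex: str, organ: str,
                      include_young: bool = False,
                      merge_tied_levels: bool = False) -> "OrderedDesign":
        """Build the ordered design for one (sex, organ) stratum.

        ``metadata`` needs columns sample_id, sex, organ, group. The
        4-month Young arm is a reference, not an intervention, and is
        excluded unless ``include_young`` (in which case it leads the
        order at its own level). ``merge_tied_levels`` collapses groups
        with identical lifespan percentages into one ordinal level.
        """
        sub = metadata[(metadata["sex"] == sex) & (metadata["organ"] == organ)]
        order = list(design.GROUP_ORDER[sex])
        groups: list[GroupSpec] = []
        if include_young:
            ids = tuple(sub.loc[sub["group"] == design.YOUNG_LABEL, "sample_id"])
            if ids:
                groups.append(GroupSpec(design.YOUNG_LABEL, -1.0, ids))
        if merge_tied_levels:
            merged: list[tuple[str, float, list[str]]] = []
            for label, pct in order:
                ids = list(sub.loc[sub["group"] == label, "sample_id"])
                if merged and merged[-1][1] == pct:
                    merged[-1] = (merged[-1][0] + "+" + label, pct, merged[-1][2] + ids)
                else:
                    merged.append((label, pct, ids))
            for label, pct, ids in merged:
                groups.append(GroupSpec(label, pct, tuple(ids)))
        else:
            for label, pct in order:
                ids = tuple(sub.loc[sub["group"] == label, "sample_id"])
                groups.append(GroupSpec(label, pct, ids))
        groups = [g for g in groups if len(g.sample_ids) > 0]
        return cls(groups=tuple(groups), sex=sex, organ=organ)


@dataclass
class TrendResult:
    """Jonckheere-Terpstra outcome for one compound in one stratum."""

    J: float
    E_J: float
    Var_J: float
    p_raw: float
    q_value: float = math.nan
    direction: str = "none"
    n_per_group: tuple[int, ...] = ()
    method: str = ""
    extra: dict = field(default_factory=dict)


def _jt_statistic(groups: list[np.ndarray]) -> float:
    j = 0.0
    for a_i in range(len(groups) - 1):
        for b_i in range(a_i + 1, len(groups)):
            a = groups[a_i][:, None]
            b = groups[b_i][None, :]
            j += float(np.sum(b > a)) + 0.5 * float(np.sum(b == a))
    return j


def _jt_null_moments(sizes: np.ndarray, pooled: np.ndarray) -> tuple[float, float]:
    """E[J] and tie-corrected Var[J] under the exchangeable null."""
    n = int(sizes.sum())
    e_j = (n * n - float(np.sum(sizes ** 2))) / 4.0
    _, t = np.unique(pooled, return_counts=True)
    t = t.astype(float)
    s = sizes.astype(float)
    term1 = (n * (n - 1) * (2 * n + 5)
             - np.sum(s * (s - 1) * (2 * s + 5))
             - np.sum(t * (t - 1) * (2 * t + 5))) / 72.0
    term2 = (np.sum(s * (s - 1) * (s - 2)) * np.sum(t * (t - 1) * (t - 2))
             / (36.0 * n * (n - 1) * (n - 2)))
    term3 = (np.sum(s * (s - 1)) * np.sum(t * (t - 1))
             / (8.0 * n * (n - 1)))
    return e_j, float(term1 + term2 + term3)


def _jt_fourth_cumulant(sizes: Sequence[int]) -> float:
    """kappa_4 of the tie-free null of J.

    By Harding's decomposition J is a sum of independent Mann-Whitney
    statistics U(M_{i-1}, n_i) (each group against the union of the
    groups before it), and for the tie-free U(m, n) null
    kappa_4 = -m n (m+n+1) (m^2 + n^2 + mn + m + n) / 120.
    """
    total = 0.0
    cum = sizes[0]
    for n_i in sizes[1:]:
        m, n = cum, n_i
        total += -m * n * (m + n + 1) * (m * m + n * n + m * n + m + n) / 120.0
        cum += n_i
    return total


def _jt_exact_counts(sizes: Sequence[int]) -> list[int]:
    """Tie-free null counts of J via convolution of Mann-Whitney counts."""
    counts = [1]
    cum = sizes[0]
    for n_i in sizes[1:]:
        mw = _mwu_null_counts(cum, n_i)
        out = [0] * (len(counts) + len(mw) - 1)
        for a, ca in enumerate(counts):
            if ca:
                for b, cb in enumerate(mw):
                    out[a + b] += ca * cb
        counts = out
        cum += n_i
    return counts


def _multiset_assignments(sizes: list[int]) -> np.ndarray:
    """All distinct assignments of group labels to N ordered slots."""
    import itertools

    n = sum(sizes)
    results: list[np.ndarray] = []
    labels = np.empty(n, dtype=np.int64)

    def rec(free: tuple[int, ...], g: int) -> None:
        if g == len(sizes):
            results.append(labels.copy())
            return
        for comb in itertools.combinations(free, sizes[g]):
            for c in comb:
                labels[c] = g
            rec(tuple(f for f in free if f not in comb), g + 1)

    rec(tuple(range(n)), 0)
    return np.array(results)


def _exact_p_with_ties(groups: list[np.ndarray], j_obs: float,
                       alternative: str) -> float:
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    if total > 1_000_000:
        raise InputSizeError(
            f"exact enumeration over {total} assignments is infeasible; "
            "use permutation or asymptotic mode")
    pooled = np.sort(np.concatenate(groups))
    assign = _multiset_assignments(sizes)  # (M, N) group labels, slots sorted by value
    m = assign.shape[0]
    j_all = np.zeros(m)
    for p in range(n):
        for q in range(p + 1, n):
            lt = assign[:, p] < assign[:, q]
            gt = assign[:, p] > assign[:, q]
            if pooled[q] > pooled[p]:
                j_all += lt.astype(float)
            elif pooled[q] == pooled[p]:
                j_all += 0.5 * lt + 0.5 * gt
    p_lo = float(np.mean(j_all <= j_obs + 1e-9))
    p_hi = float(np.mean(j_all >= j_obs - 1e-9))
    if alternative == "less":
        return p_lo
    if alternative == "greater":
        return p_hi
    return min(1.0, 2.0 * min(p_lo, p_hi))


def jonckheere(samples: Sequence[Sequence[float]], mode: str = "auto",
               alternative: str = "two-sided", n_permutations: int = 10_000,
               seed: int = 0, continuity: bool = True) -> TrendResult:
    """Jonckheere-Terpstra test for an ordered alternative.

    Parameters
    ----------
    samples : per-group value vectors, already in the design order.
    mode : {"exact", "permutation", "asymptotic", "auto"}
        exact enumerates the null (convolution when tie-free, full
        assignment enumeration when ties are present and the multinomial
        count is at most 1e6); permutation shuffles pooled values
        ``n_permutations`` times with a fixed seed; asymptotic uses the
        normal approximation with tie-corrected variance and (default) a
        continuity correction; auto picks exact for small tie-free data,
        asymptotic otherwise.
    alternative : "two-sided" (default), "greater" (increasing trend) or
        "less".
    """
    groups = [np.asarray(g, float) for g in samples]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 3:
        raise DesignError(f"need at least 3 groups, got {len(groups)}")
    if any(len(g) < 2 for g in groups):
        raise InputSizeError("each group needs at least 2 observations")
    sizes = np.array([len(g) for g in groups])
    n = int(sizes.sum())
    pooled = np.concatenate(groups)
    j_obs = _jt_statistic(groups)
    e_j, var_j = _jt_null_moments(sizes, pooled)

    direction = "up" if j_obs > e_j else ("down" if j_obs < e_j else "none")

    if np.all(pooled == pooled[0]):
        return TrendResult(J=j_obs, E_J=e_j, Var_J=0.0, p_raw=1.0,
                           direction="none", n_per_group=tuple(sizes),
                           method="degenerate")

    ties = len(np.unique(pooled)) < n
    if mode == "auto":
        mode = "exact" if (not ties and n <= 20) else "asymptotic"

    if mode == "exact":
        if ties:
            p = _exact_p_with_ties(groups, j_obs, alternative)
            method = "exact-enumeration"
        else:
            counts = _jt_exact_counts(list(sizes))
            total = sum(counts)
            ji = int(round(j_obs))
            lo = sum(counts[: ji + 1])
            hi = sum(counts[ji:])
            if alternative == "less":
                p = lo / total
            elif alternative == "greater":
                p = hi / total
            else:
                p = min(1.0, 2.0 * min(lo / total, hi / total))
            method = "exact"
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        extreme = 0
        chunk = max(1, min(n_permutations, 200_000 // max(n, 1)))
        done = 0
        bounds = np.cumsum(sizes)[:-1]
        while done < n_permutations:
            b = min(chunk, n_permutations - done)
            perm = rng.permuted(np.tile(pooled, (b, 1)), axis=1)
            parts = np.split(perm, bounds, axis=1)
            j_perm = np.zeros(b)
            for a_i in range(len(parts) - 1):
                for b_i in range(a_i + 1, len(parts)):
                    a = parts[a_i][:, :, None]
                    c = parts[b_i][:, None, :]
                    j_perm += np.sum(c > a, axis=(1, 2)) + 0.5 * np.sum(c == a, axis=(1, 2))
            if alternative == "greater":
                extreme += int(np.sum(j_perm >= j_obs - 1e-9))
            elif alternative == "less":
                extreme += int(np.sum(j_perm <= j_obs + 1e-9))
            else:
                extreme += int(np.sum(np.abs(j_perm - e_j) >= abs(j_obs - e_j) - 1e-9))
            done += b
        p = (1.0 + extreme) / (n_permutations + 1.0)
        method = "permutation"
    elif mode == "asymptotic":
        sigma = math.sqrt(max(var_j, 0.0))
        if sigma == 0.0:
            return TrendResult(J=j_obs, E_J=e_j, Var_J=var_j, p_raw=1.0,
                               direction="none", n_per_group=tuple(sizes),
                               method="degenerate")
        diff = j_obs - e_j
        cc = 0.5 if continuity else 0.0
        # excess-kurtosis Edgeworth term (the null is symmetric, so the
        # skewness term vanishes); only valid tie-free
        gamma2 = _jt_fourth_cumulant(list(sizes)) / sigma ** 4 if not ties else 0.0

        def upper_tail(z: float) -> float:
            tail = float(norm.sf(z))
            if gamma2:
                tail += float(norm.pdf(z)) * gamma2 / 24.0 * (z ** 3 - 3.0 * z)
            return min(max(tail, 0.0), 1.0)

        if alternative == "two-sided":
            z = max((abs(diff) - cc) / sigma, 0.0)
            p = 2.0 * upper_tail(z)
        elif alternative == "greater":
            p = upper_tail((diff - cc) / sigma)
        else:
            p = upper_tail(-(diff + cc) / sigma)
        p = min(1.0, p)
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return TrendResult(J=j_obs, E_J=e_j, Var_J=var_j, p_raw=float(p),
                       direction=direction, n_per_group=tuple(sizes),
                       method=method)


TREND_COLUMNS = ["compound_id", "organ", "sex", "J", "E_J", "Var_J",
                 "p_raw", "q_value", "direction", "n_total", "method"]


def trend_scan(features: pd.DataFrame, ordered: OrderedDesign,
               mode: str = "asymptotic", q_threshold: float = 0.1,
               min_per_group: int = 2, seed: int = 0,
               n_permutations: int = 10_000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-compound Jonckheere-Terpstra scan over one (organ, sex) stratum.

    ``features`` is samples x compounds (positive intensities; NaN =
    missing). Returns (results, skipped): results carries one row per
    tested compound with BH q-values computed across the compounds of
    this stratum; skipped lists compounds with insufficient per-group
    coverage and the reason. Ranks are invariant to monotone transforms,
    so raw or log intensities give identical results.
    """
    sample_sets = [[sid for sid in g.sample_ids if sid in features.index]
                   for g in ordered.groups]
    rows = []
    skipped = []
    for compound in features.columns:
        col = features[compound]
        groups = []
        ok = True
        for ids in sample_sets:
            vals = col.loc[ids].to_numpy(float)
            vals = vals[~np.isnan(vals)]
            if len(vals) < min_per_group:
                ok = False
                break
            groups.append(vals)
        if not ok or len(groups) < 3:
            skipped.append({"compound_id": compound, "organ": ordered.organ,
                            "sex": ordered.sex,
                            "reason": "insufficient non-missing coverage"})
            log.info("skipping %s (%s/%s): insufficient coverage",
                     compound, ordered.organ, ordered.sex)
            continue
        res = jonckheere(groups, mode=mode, seed=seed,
                         n_permutations=n_permutations)
        rows.append({"compound_id": compound, "organ": ordered.organ,
                     "sex": ordered.sex, "J": res.J, "E_J": res.E_J,
                     "Var_J": res.Var_J, "p_raw": res.p_raw,
                     "q_value": math.nan, "direction": res.direction,
                     "n_total": int(sum(res.n_per_group)),
                     "method": res.method})
    results = pd.DataFrame(rows, columns=TREND_COLUMNS)
    if len(results):
        results["q_value"] = benjamini_hochberg(results["p_raw"].to_numpy())
        results["significant"] = results["q_value"] < q_threshold
    else:
        results["significant"] = pd.Series(dtype=bool)
    skipped_df = pd.DataFrame(skipped, columns=["compound_id", "organ", "sex", "reason"])
    return results, skipped_df
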