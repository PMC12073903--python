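"""Jonckheere-Terpstra statistic, exact null, and the per-compound scan."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from metabotrend.stats_core import InputSizeError
from metabotrend.trend import (
    DesignError,
    GroupSpec,
    OrderedDesign,
    jonckheere,
    trend_scan,
)
from metabotrend.synthetic_data import GeneratorConfig, TrendEffect, generate


# --- independent oracles ---------------------------------------------------

def jt_double_loop(groups):
    """J by a literal double loop over all cross-group pairs."""
    j = 0.0
    for gi, gj in itertools.combinations(range(len(groups)), 2):
        for a in groups[gi]:
            for b in groups[gj]:
                if b > a:
                    j += 1.0
                elif b == a:
                    j += 0.5
    return j


def jt_enumeration_p(groups, alternative="two-sided"):
    """Exhaustive-enumeration null p-value over all distinct assignments."""
    sizes = [len(g) for g in groups]
    pooled = np.sort(np.concatenate([np.asarray(g, float) for g in groups]))
    n = len(pooled)
    j_obs = jt_double_loop(groups)
    js = []

    def rec(free, g, labels):
        if g == len(sizes):
            parts = [pooled[[i for i in range(n) if labels[i] == k]]
                     for k in range(len(sizes))]
            js.append(jt_double_loop(parts))
            return
        for comb in itertools.combinations(free, sizes[g]):
            lab = dict(labels)
            for c in comb:
                lab[c] = g
            rec(tuple(f for f in free if f not in comb), g + 1, lab)

    rec(tuple(range(n)), 0, {})
    js = np.array(js)
    p_lo = float(np.mean(js <= j_obs + 1e-9))
    p_hi = float(np.mean(js >= j_obs - 1e-9))
    if alternative == "greater":
        return p_hi
    if alternative == "less":
        return p_lo
    return min(1.0, 2.0 * min(p_lo, p_hi))


class TestJonckheere:
    def test_maximal_trend_statistic(self):
        r = jonckheere([[1, 2], [3, 4], [5, 6]], mode="exact")
        assert r.J == 12.0  # = sum over pairs n_i * n_j, every pair concordant
        assert r.direction == "up"

    def test_maximal_trend_one_sided_p(self):
        r = jonckheere([[1, 2], [3, 4], [5, 6]], mode="exact", alternative="greater")
        assert r.p_raw == pytest.approx(1 / 90)  # unique maximum of 90 assignments

    def test_degenerate_constant_data(self):
        r = jonckheere([[2, 2], [2, 2], [2, 2]])
        assert r.p_raw == 1.0
        assert r.direction == "none"

    def test_design_errors(self):
        with pytest.raises(DesignError):
            jonckheere([[1, 2], [3, 4]])
        with pytest.raises(InputSizeError):
            jonckheere([[1], [2, 3], [4, 5]])

    def test_statistic_equals_double_loop_oracle(self, rng):
        for _ in range(500):
            k = rng.integers(3, 6)
            groups = [rng.normal(size=rng.integers(2, 6)) for _ in range(k)]
            if rng.random() < 0.3:  # mix in ties
                groups = [np.round(g) for g in groups]
            r = jonckheere(groups, mode="asymptotic")
            assert r.J == pytest.approx(jt_double_loop(groups))

    def test_exact_equals_enumeration_with_ties(self):
        groups = [[1, 1, 2], [2, 3, 3], [3, 4, 4]]
        r = jonckheere(groups, mode="exact")
        assert r.method == "exact-enumeration"
        assert r.p_raw == pytest.approx(jt_enumeration_p(groups), abs=1e-12)

    def test_reversal_maps_j_to_complement(self, rng):
        """Reversing group order: J -> sum n_i n_j - J; two-sided p unchanged."""
        for _ in range(20):
            groups = [rng.normal(size=int(n)) for n in rng.integers(2, 5, size=3)]
            fwd = jonckheere(groups, mode="exact")
            rev = jonckheere(groups[::-1], mode="exact")
            sizes = [len(g) for g in groups]
            total = sum(a * b for a, b in itertools.combinations(sizes, 2))
            assert fwd.J + rev.J == pytest.approx(total)
            assert fwd.p_raw == pytest.approx(rev.p_raw, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self, rng):
        for _ in range(20):
            groups = [rng.normal(size=4) for _ in range(3)]
            base = jonckheere(groups, mode="exact")
            warped = jonckheere([np.exp(g) for g in groups], mode="exact")
            assert base.J == pytest.approx(warped.J)
            assert base.p_raw == pytest.approx(warped.p_raw, abs=1e-12)

    def test_three_modes_agree(self, rng):
        """Exact, permutation (1e5 shuffles), asymptotic within 0.02, 4+4+4."""
        for seed in range(5):
            local = np.random.default_rng(seed)
            groups = [local.normal(size=4) for _ in range(3)]
            pe = jonckheere(groups, mode="exact").p_raw
            pp = jonckheere(groups, mode="permutation", n_permutations=100_000,
                            seed=seed).p_raw
            pa = jonckheere(groups, mode="asymptotic").p_raw
            assert abs(pe - pp) < 0.02
            assert abs(pe - pa) < 0.02

    def test_permutation_deterministic_for_seed(self, rng):
        groups = [rng.normal(size=5) for _ in range(4)]
        p1 = jonckheere(groups, mode="permutation", seed=42, n_permutations=2000).p_raw
        p2 = jonckheere(groups, mode="permutation", seed=42, n_permutations=2000).p_raw
        assert p1 == p2


class TestOrderedDesign:
    def test_non_monotone_percentages_rejected(self):
        with pytest.raises(DesignError):
            OrderedDesign(groups=(
                GroupSpec("a", 5.0, ("s1", "s2")),
                GroupSpec("b", 1.0, ("s3", "s4")),
                GroupSpec("c", 9.0, ("s5", "s6"))), sex="male", organ="plasma")

    def test_from_metadata_orders_by_sex(self, small_dataset):
        female = OrderedDesign.from_metadata(small_dataset.metadata,
                                             "female", "plasma")
        male = OrderedDesign.from_metadata(small_dataset.metadata,
                                           "male", "plasma")
        assert [g.label for g in female.groups] == \
            ["Control", "17aE2", "Cana", "Aca", "Rapa", "CR"]
        assert [g.label for g in male.groups] == \
            ["Control", "Rapa", "Cana", "17aE2", "Aca", "CR"]

    def test_merge_tied_levels_collapses_female_tie(self, small_dataset):
        merged = OrderedDesign.from_metadata(small_dataset.metadata, "female",
                                             "plasma", merge_tied_levels=True)
        labels = [g.label for g in merged.groups]
        assert "17aE2+Cana" in labels
        assert len(merged.groups) == 5

    def test_young_excluded_by_default(self, small_dataset):
        d = OrderedDesign.from_metadata(small_dataset.metadata, "male", "plasma")
        assert all(g.label != "Young" for g in d.groups)
        d2 = OrderedDesign.from_metadata(small_dataset.metadata, "male",
                                         "plasma", include_young=True)
        assert d2.groups[0].label == "Young"


class TestTrendScan:
    def test_all_constant_table_nothing_significant(self, small_dataset):
        od = OrderedDesign.from_metadata(small_dataset.metadata, "male", "plasma")
        const = small_dataset.features.copy()
        const.iloc[:, :] = 1.0
        res, skipped = trend_scan(const, od)
        assert res["significant"].sum() == 0
        assert (res["p_raw"] == 1.0).all()

    def test_injected_trends_recovered(self, small_universe):
        inj = tuple(small_universe["compound_id"].iloc[:30])
        cfg = GeneratorConfig(seed=3, organs=("plasma",), sexes=("male",),
                              compounds=small_universe, young_mimic=False,
                              trend_spec=(TrendEffect(inj, 0.02),))
        ds = generate(cfg)
        od = OrderedDesign.from_metadata(ds.metadata, "male", "plasma")
        res, _ = trend_scan(ds.features, od)
        hits = set(res.loc[res["significant"], "compound_id"])
        assert len(hits & set(inj)) / len(inj) >= 0.8
        directions = res.set_index("compound_id").loc[list(hits & set(inj)),
                                                      "direction"]
        assert (directions == "up").mean() > 0.95

    def test_insufficient_coverage_goes_to_skip_log(self, small_dataset):
        od = OrderedDesign.from_metadata(small_dataset.metadata, "male", "plasma")
        feats = small_dataset.features.copy()
        first = feats.columns[0]
        feats.loc[list(od.groups[1].sample_ids), first] = np.nan
        res, skipped = trend_scan(feats, od)
        assert first in set(skipped["compound_id"])
        assert first not in set(res["compound_id"])
        # no silent drops: every compound is in exactly one of the two tables
        assert len(res) + len(skipped) == feats.shape[1]
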