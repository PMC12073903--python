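"""Class enrichment, directional fractions, and subclass breakdowns."""

import numpy as np
import pandas as pd
import pytest

from metabotrend.enrichment import (
    amino_acid_breakdown,
    class_enrichment,
    subclass_breakdown,
    tissue_class_fractions,
)
from metabotrend.synthetic_data import GeneratorConfig, TrendEffect, generate
from metabotrend.trend import OrderedDesign, trend_scan


def make_results(per_class, organ="plasma", sex="male", contrast="CR"):
    """Build a per-compound results frame from {class: [(p, q, dir), ...]}."""
    rows = []
    ann_rows = []
    i = 0
    for cls, members in per_class.items():
        for p, q, direction in members:
            cid = f"X{i:03d}"
            rows.append({"compound_id": cid, "organ": organ, "sex": sex,
                         "contrast": contrast, "p_raw": p, "q_value": q,
                         "direction": direction})
            ann_rows.append({"compound_id": cid, "name": cid,
                             "superclass": "lipid", "subclass": cls,
                             "lipid_shorthand": "", "aa_category": ""})
            i += 1
    return pd.DataFrame(rows), pd.DataFrame(ann_rows)


class TestClassEnrichment:
    def test_directional_fraction_arithmetic(self):
        members = ([(0.001, 0.01, "up")] * 4 + [(0.001, 0.01, "down")]
                   + [(0.5, 0.8, "up")] * 5)
        results, ann = make_results({"TAG": members})
        out = class_enrichment(results, ann)
        row = out.iloc[0]
        assert row["n_members"] == 10
        assert row["n_up_sig"] == 4 and row["n_down_sig"] == 1
        assert row["directional_fraction"] == pytest.approx(0.3)

    def test_saturated_class_fully_up(self):
        results, ann = make_results({"PC": [(1e-5, 1e-4, "up")] * 8})
        out = class_enrichment(results, ann)
        assert out.iloc[0]["enrichment_p"] < 0.05
        assert out.iloc[0]["significant"]
        assert out.iloc[0]["directional_fraction"] == pytest.approx(1.0)

    def test_small_classes_skipped(self):
        results, ann = make_results({"tiny": [(0.001, 0.01, "up")] * 2,
                                     "ok": [(0.4, 0.6, "up")] * 5})
        out = class_enrichment(results, ann, min_class_size=3)
        assert set(out["class_name"]) == {"ok"}

    def test_null_classes_reject_at_alpha(self, rng):
        """Uniform member p-values: ~5% of classes flagged (99% binomial band)."""
        n_rep, size = 2000, 10
        hits = 0
        for _ in range(n_rep):
            p = rng.random(size)
            members = [(float(v), 1.0, "up") for v in p]
            results, ann = make_results({"C": members})
            out = class_enrichment(results, ann)
            hits += int(out.iloc[0]["significant"])
        assert 0.038 <= hits / n_rep <= 0.062

    def test_raw_sig_rule_changes_counts(self):
        members = [(0.01, 0.2, "up")] * 5  # raw-significant, not q-significant
        results, ann = make_results({"FA": members})
        by_q = class_enrichment(results, ann, sig_rule="q:0.1")
        by_raw = class_enrichment(results, ann, sig_rule="raw:0.05")
        assert by_q.iloc[0]["n_up_sig"] == 0
        assert by_raw.iloc[0]["n_up_sig"] == 5

    def test_shuffled_labels_destroy_signal(self, rng):
        """Concentrated signal disappears when compound->class labels shuffle."""
        per_class = {"sig": [(1e-6, 1e-5, "up")] * 10}
        for k in range(6):
            per_class[f"null{k}"] = [(float(v), 1.0, "up")
                                     for v in rng.random(10)]
        results, ann = make_results(per_class)
        n_obs = int(class_enrichment(results, ann)["significant"].sum())
        assert n_obs >= 1
        shuffled_counts = []
        for _ in range(50):
            ann_s = ann.copy()
            ann_s["subclass"] = rng.permutation(ann_s["subclass"].to_numpy())
            out = class_enrichment(results, ann_s)
            shuffled_counts.append(int(out["significant"].sum()))
        assert np.median(shuffled_counts) < n_obs

    def test_member_counts_partition_annotated_compounds(self, small_dataset):
        res, _ = trend_scan(
            small_dataset.features,
            OrderedDesign.from_metadata(small_dataset.metadata, "male", "plasma"))
        res = res.assign(contrast="trend")
        out = class_enrichment(res, small_dataset.annotations, min_class_size=1)
        ann = small_dataset.annotations
        annotated = res["compound_id"].isin(
            ann.loc[ann["subclass"] != "unclassified", "compound_id"]).sum()
        assert out["n_members"].sum() == annotated


class TestTissueFractions:
    def test_fraction_arithmetic(self, small_dataset):
        res, _ = trend_scan(
            small_dataset.features,
            OrderedDesign.from_metadata(small_dataset.metadata, "male", "plasma"))
        out = tissue_class_fractions(res, small_dataset.annotations)
        total = len(res[res["compound_id"].isin(
            small_dataset.annotations.loc[
                small_dataset.annotations["subclass"] != "unclassified",
                "compound_id"])])
        recomputed = (out["n_significant"] / total).to_numpy()
        assert out["tissue_fraction"].to_numpy() == pytest.approx(recomputed)

    def test_fractions_bounded_by_one_per_stratum(self, small_dataset):
        res, _ = trend_scan(
            small_dataset.features,
            OrderedDesign.from_metadata(small_dataset.metadata, "male", "plasma"))
        out = tissue_class_fractions(res, small_dataset.annotations)
        assert out.groupby(["organ", "sex"])["tissue_fraction"].sum().max() <= 1.0

    def test_no_significant_means_zero_fractions(self, small_dataset):
        res, _ = trend_scan(
            small_dataset.features,
            OrderedDesign.from_metadata(small_dataset.metadata, "male", "plasma"))
        res = res.assign(q_value=1.0)
        out = tissue_class_fractions(res, small_dataset.annotations)
        assert (out["tissue_fraction"] == 0).all()


class TestSubclassBreakdown:
    def test_pufa_tag_injection_dominates_target_panel(self, universe):
        """PUFA TAG trends injected only in male inguinal fat concentrate there."""
        from metabotrend.annotations import descriptors_from_table, unsaturation_bin
        desc = descriptors_from_table(universe)
        pufa_tags = tuple(cid for cid, d in desc.items()
                          if d.lipid_class == "TAG" and not d.is_oxidized
                          and d.total_double_bonds >= 6)
        assert len(pufa_tags) >= 10
        for seed in (0, 1, 2):
            cfg = GeneratorConfig(
                seed=seed, organs=("inguinal fat", "liver"), sexes=("male",),
                compounds=universe, young_mimic=False,
                trend_spec=(TrendEffect(pufa_tags, 0.02,
                                        organs=("inguinal fat",)),))
            ds = generate(cfg)
            frames = []
            for organ in cfg.organs:
                od = OrderedDesign.from_metadata(ds.metadata, "male", organ)
                res, _ = trend_scan(ds.features, od)
                frames.append(res)
            res = pd.concat(frames, ignore_index=True)
            out = subclass_breakdown(res, ds.annotations, lipid_class="TAG")
            ing = out[(out["organ"] == "inguinal fat")
                      & (out["unsaturation_bin"] == "pufa_enriched")
                      & (out["direction"] == "up")]
            others = out.drop(ing.index)
            assert ing["n"].sum() > (others["n"].max() if len(others) else 0)

    def test_empty_significant_set_gives_empty_table(self, small_dataset):
        res, _ = trend_scan(
            small_dataset.features,
            OrderedDesign.from_metadata(small_dataset.metadata, "male", "plasma"))
        res = res.assign(q_value=1.0)
        out = subclass_breakdown(res, small_dataset.annotations, "TAG")
        assert len(out) == 0


class TestAminoAcidBreakdown:
    def test_counts_only_amino_acid_superclass(self, small_dataset):
        res, _ = trend_scan(
            small_dataset.features,
            OrderedDesign.from_metadata(small_dataset.metadata, "male", "plasma"))
        out = amino_acid_breakdown(res, small_dataset.annotations)
        if len(out):
            assert set(out["aa_category"]) <= {
                "dipeptide", "proteinogenic", "non_proteinogenic", "derivative"}
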