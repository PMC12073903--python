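"""Chemical-class set enrichment and class-level summaries.

A class (annotation subclass) is enriched when its members' RAW
univariate p-values are non-uniform, tested with the one-sample
Kolmogorov-Smirnov statistic against Uniform(0,1) — the set statistic of
chemical-similarity enrichment analysis, with set membership taken from
the annotation subclass directly (no structure-similarity clustering).

The directional regulation fraction for a class is
(n significantly up - n significantly down) / class size, in [-1, 1].
Per-compound significance inside the counts defaults to BH q < 0.1; a
raw-p rule is available (`sig_rule="raw:0.05"`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats_core import benjamini_hochberg, ks_uniform
from .annotations import (
    chain_length_bin,
    unsaturation_bin,
    descriptors_from_table,
    ChainLengthBin,
    UnsaturationBin,
)

__all__ = [
    "class_enrichment",
    "tissue_class_fractions",
    "subclass_breakdown",
    "amino_acid_breakdown",
]

log = logging.getLogger(__name__)

CLASS_SUMMARY_COLUMNS = [
    "class_name", "organ", "sex", "contrast", "n_members", "n_up_sig",
    "n_down_sig", "enrichment_p", "directional_fraction", "significant",
]


def _parse_sig_rule(sig_rule: str) -> tuple[str, float]:
    kind, _, thr = sig_rule.partition(":")
    if kind not in ("q", "raw") or not thr:
        raise ValueError(f"sig_rule must look like 'q:0.1' or 'raw:0.05', got {sig_rule!r}")
    return kind, float(thr)


def _is_significant(df: pd.DataFrame, sig_rule: str) -> pd.Series:
    kind, thr = _parse_sig_rule(sig_rule)
    col = "q_value" if kind == "q" else "p_raw"
    return df[col] < thr


def class_enrichment(results: pd.DataFrame, annotations: pd.DataFrame,
                     min_class_size: int = 3, ks_alpha: float = 0.05,
                     sig_rule: str = "q:0.1", ks_mode: str = "auto",
                     adjust_across_classes: bool = False) -> pd.DataFrame:
    """Subclass enrichment over per-compound test results.

    ``results`` needs columns compound_id, p_raw, q_value, direction and
    the stratum labels organ, sex, contrast (the contrast column may
    name a treatment comparison or the trend test). Returns one row per
    (organ, sex, contrast, subclass) of at least ``min_class_size``
    members; smaller classes are skipped and logged. ``significant``
    flags enrichment_p < ks_alpha (raw by default; ``adjust_across_classes``
    applies BH over classes within each stratum first).
    """
    ann = annotations.set_index("compound_id")["subclass"]
    df = results.copy()
    df["subclass"] = df["compound_id"].map(ann)
    df = df[df["subclass"].notna() & (df["subclass"] != "unclassified")]
    sig = _is_significant(df, sig_rule)
    rows = []
    for (organ, sex, contrast, subclass), grp in df.groupby(
            ["organ", "sex", "contrast", "subclass"], sort=True):
        n = len(grp)
        if n < min_class_size:
            log.info("skipping class %s (%s/%s/%s): %d members < %d",
                     subclass, organ, sex, contrast, n, min_class_size)
            continue
        ks = ks_uniform(grp["p_raw"].to_numpy(), mode=ks_mode)
        s = sig.loc[grp.index]
        n_up = int(((grp["direction"] == "up") & s).sum())
        n_down = int(((grp["direction"] == "down") & s).sum())
        rows.append({
            "class_name": subclass, "organ": organ, "sex": sex,
            "contrast": contrast, "n_members": n, "n_up_sig": n_up,
            "n_down_sig": n_down, "enrichment_p": ks.p_raw,
            "directional_fraction": (n_up - n_down) / n,
            "significant": False,
        })
    out = pd.DataFrame(rows, columns=CLASS_SUMMARY_COLUMNS)
    if len(out):
        if adjust_across_classes:
            adj = out.groupby(["organ", "sex", "contrast"])["enrichment_p"] \
                     .transform(lambda p: benjamini_hochberg(p.to_numpy()))
            out["significant"] = adj < ks_alpha
        else:
            out["significant"] = out["enrichment_p"] < ks_alpha
    return out


def tissue_class_fractions(trend_results: pd.DataFrame,
                           annotations: pd.DataFrame,
                           q_threshold: float = 0.1) -> pd.DataFrame:
    """Per-class significant-compound fractions normalised per tissue.

    For each (subclass, organ, sex, direction): the number of class
    members with trend q < ``q_threshold`` in that direction divided by
    the total number of compounds measured in that (organ, sex). Summed
    over classes and directions the fractions are bounded by 1.
    """
    ann = annotations.set_index("compound_id")["subclass"]
    df = trend_results.copy()
    df["subclass"] = df["compound_id"].map(ann)
    df = df[df["subclass"].notna() & (df["subclass"] != "unclassified")]
    rows = []
    for (organ, sex), stratum in df.groupby(["organ", "sex"], sort=True):
        total = len(stratum)
        sig = stratum[stratum["q_value"] < q_threshold]
        for subclass, grp in stratum.groupby("subclass", sort=True):
            for direction in ("up", "down"):
                k = int(((sig["subclass"] == subclass)
                         & (sig["direction"] == direction)).sum())
                rows.append({
                    "class_name": subclass, "organ": organ, "sex": sex,
                    "direction": direction, "n_members": len(grp),
                    "n_significant": k,
                    "tissue_fraction": k / total if total else 0.0,
                })
    return pd.DataFrame(rows, columns=["class_name", "organ", "sex", "direction",
                                       "n_members", "n_significant",
                                       "tissue_fraction"])


def subclass_breakdown(trend_results: pd.DataFrame, annotations: pd.DataFrame,
                       lipid_class: str = "TAG", q_threshold: float = 0.1,
                       include_oxidized: bool = False) -> pd.DataFrame:
    """Chain-length x unsaturation x direction counts of significant lipids.

    Cross-tabulates compounds of one lipid class (TAG, DAG or PC) with a
    significant trend, per (organ, sex), into total-carbon and
    total-double-bond bins. Returns a long table; empty when nothing is
    significant.
    """
    descriptors = descriptors_from_table(annotations)
    keep = {cid: d for cid, d in descriptors.items()
            if d.lipid_class == lipid_class
            and (include_oxidized or not d.is_oxidized)
            and d.total_carbons > 0}
    df = trend_results[trend_results["compound_id"].isin(keep)
                       & (trend_results["q_value"] < q_threshold)
                       & trend_results["direction"].isin(["up", "down"])]
    rows = []
    for (organ, sex), grp in df.groupby(["organ", "sex"], sort=True):
        counts: dict[tuple[str, str, str], int] = {}
        for cid, direction in zip(grp["compound_id"], grp["direction"]):
            d = keep[cid]
            key = (chain_length_bin(d).value, unsaturation_bin(d).value, direction)
            counts[key] = counts.get(key, 0) + 1
        for cb in ChainLengthBin:
            for ub in UnsaturationBin:
                for direction in ("up", "down"):
                    k = counts.get((cb.value, ub.value, direction), 0)
                    if k:
                        rows.append({
                            "lipid_class": lipid_class, "organ": organ,
                            "sex": sex, "chain_bin": cb.value,
                            "unsaturation_bin": ub.value,
                            "direction": direction, "n": k,
                        })
    return pd.DataFrame(rows, columns=["lipid_class", "organ", "sex",
                                       "chain_bin", "unsaturation_bin",
                                       "direction", "n"])


def amino_acid_breakdown(trend_results: pd.DataFrame,
                         annotations: pd.DataFrame,
                         q_threshold: float = 0.1) -> pd.DataFrame:
    """Significant-trend counts by amino-acid category per (organ, sex)."""
    ann = annotations.set_index("compound_id")
    aa = ann[ann["superclass"] == "amino acid/peptide"]["aa_category"]
    df = trend_results[trend_results["compound_id"].isin(aa.index)
                       & (trend_results["q_value"] < q_threshold)
                       & trend_results["direction"].isin(["up", "down"])].copy()
    df["aa_category"] = df["compound_id"].map(aa)
    out = (df.groupby(["organ", "sex", "aa_category", "direction"], sort=True)
             .size().reset_index(name="n"))
    return out
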