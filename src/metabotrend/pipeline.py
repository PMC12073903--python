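"""Pipeline orchestration: univariate pass and trend pass over all strata.

Strata are fully independent (organ x sex); multiple-testing correction
is applied across compounds within each (organ, sex, contrast) family.
Unannotated compounds are tested but excluded from class-level
summaries. Output tables have fixed schemas and deterministic row
order, so re-running a configuration reproduces byte-identical files.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design
from .stats_core import benjamini_hochberg, mann_whitney_u, InputSizeError
from .trend import OrderedDesign, trend_scan
from .enrichment import (
    class_enrichment,
    tissue_class_fractions,
    subclass_breakdown,
    amino_acid_breakdown,
)

__all__ = ["RunConfig", "PipelineError", "run_univariate", "run_trend",
           "load_tables", "write_tables"]

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


class PipelineError(ValueError):
    """Raised for unusable inputs (missing control arm, unknown labels, ...)."""


@dataclass
class RunConfig:
    """Thresholds, test modes, and paths for one analysis run."""

    feature_table: str | None = None
    metadata: str | None = None
    annotations: str | None = None
    outdir: str = "results"
    q_univariate: float = 0.1
    q_trend: float = 0.1
    ks_alpha: float = 0.05
    min_class_size: int = 3
    sig_rule: str = "q:0.1"
    mwu_mode: str = "asymptotic"
    trend_mode: str = "asymptotic"
    include_young_in_trend: bool = False
    merge_tied_levels: bool = False
    seed: int = 0
    group_order: dict = field(default_factory=lambda: {
        sex: [list(g) for g in design.GROUP_ORDER[sex]] for sex in design.SEXES})

    def __post_init__(self) -> None:
        for name in ("q_univariate", "q_trend", "ks_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def load_tables(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    from .annotations import read_annotation_table

    features = pd.read_csv(config.feature_table, sep="\t", index_col=0)
    metadata = pd.read_csv(config.metadata, sep="\t", dtype={"sample_id": str})
    annotations = read_annotation_table(config.annotations)
    return features, metadata, annotations


def _validate_inputs(features: pd.DataFrame, metadata: pd.DataFrame) -> None:
    common = set(features.index) & set(metadata["sample_id"])
    if not common:
        raise PipelineError("no overlap between feature-table samples and metadata")
    known = {design.CONTROL_LABEL, design.YOUNG_LABEL} | set(design.TREATMENTS)
    unknown = sorted(set(metadata["group"]) - known)
    if unknown:
        raise PipelineError(
            f"unknown treatment labels {unknown}; valid labels are {sorted(known)}")


UNIVARIATE_COLUMNS = ["compound_id", "organ", "sex", "contrast", "U", "p_raw",
                      "q_value", "direction", "n_treated", "n_control", "method"]


def run_univariate(features: pd.DataFrame, metadata: pd.DataFrame,
                   annotations: pd.DataFrame, config: RunConfig | None = None
                   ) -> dict[str, pd.DataFrame]:
    """Each treatment and the Young arm versus the 12-month control.

    Per (organ, sex, contrast): Mann-Whitney U per compound with pairwise
    missing-value exclusion, BH across compounds within the stratum,
    then superclass significant-proportion and subclass enrichment
    summaries. Returns {"results", "superclass_fractions", "enrichment",
    "skipped"}.
    """
    config = config or RunConfig()
    _validate_inputs(features, metadata)
    meta = metadata[metadata["sample_id"].isin(features.index)]
    superclass = annotations.set_index("compound_id")["superclass"]

    rows: list[dict] = []
    skipped: list[dict] = []
    strata = sorted(set(zip(meta["organ"], meta["sex"])))
    for organ, sex in strata:
        sub = meta[(meta["organ"] == organ) & (meta["sex"] == sex)]
        control_ids = list(sub.loc[sub["group"] == design.CONTROL_LABEL, "sample_id"])
        if len(control_ids) < 2:
            raise PipelineError(f"stratum ({organ}, {sex}) lacks a control group")
        contrasts = [g for g in sub["group"].unique()
                     if g != design.CONTROL_LABEL]
        order = [design.YOUNG_LABEL] + design.ordered_labels(sex)
        contrasts = [g for g in order if g in contrasts]
        ctrl = features.loc[control_ids]
        for contrast in contrasts:
            treated_ids = list(sub.loc[sub["group"] == contrast, "sample_id"])
            trt = features.loc[treated_ids]
            for compound in features.columns:
                x = trt[compound].to_numpy(float)
                y = ctrl[compound].to_numpy(float)
                x, y = x[~np.isnan(x)], y[~np.isnan(y)]
                if len(x) < 2 or len(y) < 2:
                    skipped.append({"compound_id": compound, "organ": organ,
                                    "sex": sex, "contrast": contrast,
                                    "reason": "insufficient non-missing coverage"})
                    continue
                try:
                    res = mann_whitney_u(x, y, mode=config.mwu_mode)
                except InputSizeError:
                    skipped.append({"compound_id": compound, "organ": organ,
                                    "sex": sex, "contrast": contrast,
                                    "reason": "test infeasible"})
                    continue
                rows.append({"compound_id": compound, "organ": organ,
                             "sex": sex, "contrast": contrast,
                             "U": res.statistic, "p_raw": res.p_raw,
                             "q_value": math.nan, "direction": res.direction,
                             "n_treated": len(x), "n_control": len(y),
                             "method": res.method})
    results = pd.DataFrame(rows, columns=UNIVARIATE_COLUMNS)
    if len(results):
        results["q_value"] = (
            results.groupby(["organ", "sex", "contrast"])["p_raw"]
                   .transform(lambda p: benjamini_hochberg(p.to_numpy())))
        results["significant"] = results["q_value"] < config.q_univariate
    else:
        results["significant"] = pd.Series(dtype=bool)

    # Per-superclass significant proportions (matrix behind the heatmap of
    # univariate results): fraction of class members significant, and the
    # same count normalised to all compounds tested in the stratum.
    frac_rows = []
    if len(results):
        ann_sup = results["compound_id"].map(superclass).fillna("other")
        results_sup = results.assign(superclass=ann_sup)
        for (organ, sex, contrast), grp in results_sup.groupby(
                ["organ", "sex", "contrast"], sort=True):
            total = len(grp)
            for sup, g in grp.groupby("superclass", sort=True):
                n_sig = int(g["significant"].sum())
                frac_rows.append({
                    "organ": organ, "sex": sex, "contrast": contrast,
                    "superclass": sup, "n_members": len(g), "n_sig": n_sig,
                    "frac_of_class": n_sig / len(g),
                    "frac_of_organ": n_sig / total if total else 0.0,
                })
    superclass_fractions = pd.DataFrame(
        frac_rows, columns=["organ", "sex", "contrast", "superclass",
                            "n_members", "n_sig", "frac_of_class",
                            "frac_of_organ"])

    enrichment = class_enrichment(results, annotations,
                                  min_class_size=config.min_class_size,
                                  ks_alpha=config.ks_alpha,
                                  sig_rule=config.sig_rule)
    skipped_df = pd.DataFrame(
        skipped, columns=["compound_id", "organ", "sex", "contrast", "reason"])
    return {"results": results, "superclass_fractions": superclass_fractions,
            "enrichment": enrichment, "skipped": skipped_df}


def run_trend(features: pd.DataFrame, metadata: pd.DataFrame,
              annotations: pd.DataFrame, config: RunConfig | None = None
              ) -> dict[str, pd.DataFrame]:
    """Jonckheere-Terpstra scan per stratum plus class-level summaries.

    Emits per-compound trend results (BH within organ x sex), per-sex
    up/down totals, per-tissue class fractions, TAG/DAG/PC chain-length x
    unsaturation breakdowns, and the amino-acid category breakdown.
    """
    config = config or RunConfig()
    _validate_inputs(features, metadata)
    meta = metadata[metadata["sample_id"].isin(features.index)]
    all_results = []
    all_skipped = []
    strata = sorted(set(zip(meta["organ"], meta["sex"])))
    for organ, sex in strata:
        ordered = OrderedDesign.from_metadata(
            meta, sex=sex, organ=organ,
            include_young=config.include_young_in_trend,
            merge_tied_levels=config.merge_tied_levels)
        res, skp = trend_scan(features, ordered, mode=config.trend_mode,
                              q_threshold=config.q_trend, seed=config.seed)
        all_results.append(res)
        all_skipped.append(skp)
    results = pd.concat(all_results, ignore_index=True) if all_results else pd.DataFrame()
    skipped = pd.concat(all_skipped, ignore_index=True) if all_skipped else pd.DataFrame()

    sig = results[results["q_value"] < config.q_trend]
    updown = (sig.groupby(["organ", "sex", "direction"], sort=True)
                 .size().reset_index(name="n"))
    # per-sex totals: compounds significant in at least one organ
    sex_rows = []
    for sex, grp in sig.groupby("sex", sort=True):
        sex_rows.append({"sex": sex,
                         "n_compounds_any_organ": grp["compound_id"].nunique(),
                         "n_up": int((grp["direction"] == "up").sum()),
                         "n_down": int((grp["direction"] == "down").sum())})
    sex_totals = pd.DataFrame(sex_rows, columns=["sex", "n_compounds_any_organ",
                                                 "n_up", "n_down"])

    class_fractions = tissue_class_fractions(results, annotations,
                                             q_threshold=config.q_trend)
    breakdowns = {
        cls: subclass_breakdown(results, annotations, lipid_class=cls,
                                q_threshold=config.q_trend)
        for cls in ("TAG", "DAG", "PC")
    }
    aa = amino_acid_breakdown(results, annotations, q_threshold=config.q_trend)
    return {"results": results, "skipped": skipped, "updown_counts": updown,
            "sex_totals": sex_totals, "class_fractions": class_fractions,
            "breakdown_TAG": breakdowns["TAG"], "breakdown_DAG": breakdowns["DAG"],
            "breakdown_PC": breakdowns["PC"], "aa_breakdown": aa}


def write_tables(tables: dict[str, pd.DataFrame], outdir, config: RunConfig | None = None,
                 prefix: str = "") -> list[Path]:
    """Write result tables as TSV plus a JSON run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = outdir / f"{prefix}{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        written.append(path)
    if config is not None:
        manifest = {"config": asdict(config), "tables": [p.name for p in written]}
        mpath = outdir / f"{prefix}manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(mpath)
    return written
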