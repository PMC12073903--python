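"""Synthetic multi-organ, two-sex metabolomics data with known trend structure.

The generator emulates the study design end to end: two sexes, six
organs, a 12-month control arm (25 males / 23 females), five
lifespan-extending interventions with 12 mice per sex per treatment, and
a 4-month Young reference arm. Intensities are log-normal:

    log10 intensity = baseline + subclass offset
                      + beta * lifespan_pct        (trend compounds)
                      + young shift                (Young arm only)
                      + Normal(0, noise_sd)

so a compound with beta = 0.02 per percent and noise_sd = 0.5 log units
carries a CR-vs-control log-fold of ~0.66-0.8 depending on sex. Trend
effects are linear in lifespan percent (the simplest monotone choice;
the trend test only consumes monotonicity). Missing values are injected
completely at random. The ground-truth ledger records every compound's
true beta per (organ, sex) so recovery and calibration are checkable
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import design
from .annotations import build_annotation_table

__all__ = [
    "TrendEffect",
    "GeneratorConfig",
    "SyntheticDataset",
    "default_compound_universe",
    "default_trend_spec",
    "generate",
    "worked_example_fixture",
]


@dataclass(frozen=True)
class TrendEffect:
    """A monotone log-intensity effect on a compound set.

    ``target`` selects compounds by annotation subclass (string) or by an
    explicit compound-id tuple. ``beta`` is log10-intensity per percent
    of lifespan extension (sign gives the direction). ``organs``/``sexes``
    restrict the effect; None means all.
    """

    target: str | tuple[str, ...]
    beta: float
    organs: tuple[str, ...] | None = None
    sexes: tuple[str, ...] | None = None

    def selects(self, compound_id: str, subclass: str, organ: str, sex: str) -> bool:
        if self.organs is not None and organ not in self.organs:
            return False
        if self.sexes is not None and sex not in self.sexes:
            return False
        if isinstance(self.target, str):
            return subclass == self.target
        return compound_id in self.target


FAT = ("inguinal fat", "gonadal fat")


def default_trend_spec(beta: float = 0.02) -> tuple[TrendEffect, ...]:
    """Class-structured trend effects emulating the study's main findings.

    Neutral glycerolipids fall in plasma and liver but rise in adipose
    tissue and kidney; phosphatidylcholines fall in plasma and respond
    male-biased elsewhere; free fatty acids rise in males across organs;
    sphingolipids and ceramides rise in kidney; dipeptides fall in
    muscle and rise in male liver/kidney/inguinal fat; carbohydrates
    fall in plasma and liver. Male effects are deliberately broader so
    the male/female significance asymmetry is reproducible.
    """
    b = beta
    return (
        TrendEffect("TAG", -b, organs=("plasma", "liver")),
        TrendEffect("DAG", -b, organs=("plasma", "liver")),
        TrendEffect("TAG", b, organs=FAT + ("kidney",), sexes=("male",)),
        TrendEffect("TAG", b, organs=("gonadal fat",), sexes=("female",)),
        TrendEffect("DAG", b, organs=FAT),
        TrendEffect("PC", -b, organs=("plasma",)),
        TrendEffect("PC", b, organs=("liver", "inguinal fat"), sexes=("male",)),
        TrendEffect("PC", b, organs=("gonadal fat",), sexes=("female",)),
        TrendEffect("LPC", -b, organs=("liver", "gastrocnemius muscle")),
        TrendEffect("FA", b, organs=design.ORGANS, sexes=("male",)),
        TrendEffect("SM", b, organs=("kidney",)),
        TrendEffect("Cer", b, organs=("kidney",)),
        TrendEffect("dipeptides", -b, organs=("gastrocnemius muscle",)),
        TrendEffect("dipeptides", b, organs=("liver", "kidney", "inguinal fat"),
                    sexes=("male",)),
        TrendEffect("proteinogenic amino acids", b, organs=("kidney",),
                    sexes=("male",)),
        TrendEffect("carbohydrates", -b, organs=("plasma", "liver")),
    )


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    seed: int = 0
    n_control: dict = field(default_factory=lambda: {"male": 25, "female": 23})
    n_per_treatment: int = 12
    n_young: int = 12
    organs: tuple[str, ...] = design.ORGANS
    sexes: tuple[str, ...] = design.SEXES
    baseline_log_mean: float = 5.0
    noise_sd: float = 0.5
    trend_spec: tuple[TrendEffect, ...] = field(default_factory=default_trend_spec)
    young_mimic: bool = True  # Young arm shifted like the strongest intervention (CR)
    missing_rate: float = 0.02
    compounds: pd.DataFrame | None = None  # annotation table; default universe if None

    def __post_init__(self) -> None:
        if not (11 <= self.n_per_treatment <= 14):
            raise ValueError("n_per_treatment must lie in [11, 14]")
        if not (0.0 <= self.missing_rate <= 0.2):
            raise ValueError("missing_rate must lie in [0, 0.2]")
        for sex, n in self.n_control.items():
            if n <= 0:
                raise ValueError(f"n_control[{sex!r}] must be positive")
        if self.n_young < 0:
            raise ValueError("n_young must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for eff in self.trend_spec:
            if not np.isfinite(eff.beta):
                raise ValueError("trend beta must be finite")


class SyntheticDataset(NamedTuple):
    features: pd.DataFrame     # samples x compounds, positive intensities
    metadata: pd.DataFrame     # sample_id, mouse_id, sex, organ, group, lifespan_pct
    annotations: pd.DataFrame  # standard annotation table
    truth: pd.DataFrame        # compound_id, organ, sex, beta, direction


# ---------------------------------------------------------------------------
# Compound universe
# ---------------------------------------------------------------------------

_NONLIPID_UNIVERSE: dict[tuple[str, str], tuple[str, ...]] = {
    ("amino acid/peptide", "proteinogenic amino acids"): (
        "alanine", "arginine", "asparagine", "aspartic acid", "cysteine",
        "glutamic acid", "glutamine", "glycine", "histidine", "isoleucine",
        "leucine", "lysine", "methionine", "phenylalanine", "proline",
        "serine", "threonine", "tryptophan", "tyrosine", "valine"),
    ("amino acid/peptide", "dipeptides"): (
        "glycylglycine", "glycylleucine", "alanylalanine", "glycylproline",
        "leucylglycine", "alanylglycine", "glycylvaline", "seryltyrosine",
        "valylleucine", "prolylglycine", "glutamylvaline", "lysylleucine",
        "threonylserine", "histidylglycine", "methionylalanine"),
    ("amino acid/peptide", "amino acid derivatives"): (
        "N-acetylglycine", "N-acetylalanine", "N-acetylleucine",
        "N-acetylmethionine", "3-methylhistidine", "1-methylhistidine",
        "N-acetylserine", "dimethylglycine", "hydroxyproline",
        "N-acetyllysine", "methionine sulfoxide", "N-acetylglutamine",
        "trimethyllysine", "N-formylmethionine", "hydroxylysine"),
    ("amino acid/peptide", "non-proteinogenic amino acids"): (
        "taurine", "ornithine", "citrulline", "beta-alanine",
        "gamma-aminobutyric acid", "sarcosine", "homoserine", "homocysteine",
        "kynurenine", "creatine", "betaine", "aminoadipic acid",
        "N-omega-acetylhistamine", "5-aminovaleric acid"),
    ("carbohydrate", "carbohydrates"): (
        "glucose", "fructose", "galactose", "maltose", "lactose", "sucrose",
        "trehalose", "sorbitol", "ribitol", "myo-inositol", "xylose",
        "arabinose", "mannose", "ribose", "fucose", "sophorose",
        "fructose-6-phosphate", "fructose-1-phosphate", "glucose-6-phosphate",
        "phosphogluconic acid", "galactonic acid", "threonic acid",
        "glyceric acid", "erythritol", "xylitol", "maltotriose",
        "deoxypentitol", "galacto-N-biose", "glucuronic acid", "N-acetylglucosamine"),
    ("organic acid", "organic acids"): (
        "citric acid", "succinic acid", "fumaric acid", "malic acid",
        "lactic acid", "pyruvic acid", "alpha-ketoglutaric acid",
        "oxalic acid", "glycolic acid", "isocitric acid", "itaconic acid",
        "2-hydroxybutyric acid", "3-hydroxybutyric acid", "benzoic acid",
        "hippuric acid", "azelaic acid", "adipic acid", "pimelic acid",
        "suberic acid", "quinic acid"),
    ("organic acid", "bile acids"): (
        "taurocholic acid", "tauroursodeoxycholic acid", "deoxycholic acid",
        "cholic acid", "chenodeoxycholic acid", "taurodeoxycholic acid",
        "glycocholic acid", "ursodeoxycholic acid"),
    ("organoheterocyclic", "organoheterocyclics"): (
        "niacinamide", "indole-3-lactic acid", "indoxyl sulfate",
        "urocanic acid", "pyridoxine", "pyridoxal", "quinolinic acid",
        "picolinic acid", "melatonin", "serotonin", "indole-3-propionic acid",
        "tryptamine", "caffeine", "theobromine", "allantoin"),
    ("nucleotide", "nucleotides"): (
        "adenine", "adenosine", "AMP", "ADP", "guanine", "guanosine", "GMP",
        "cytosine", "cytidine", "CMP", "uracil", "uridine", "UMP", "thymine",
        "thymidine", "inosine", "hypoxanthine", "xanthine", "uric acid",
        "xanthosine"),
    ("other", "unclassified small molecules"): (
        "glycerol", "ethanolamine", "choline", "phosphocholine", "urea",
        "putrescine", "spermidine", "spermine", "pantothenic acid",
        "ascorbic acid"),
}

# per class: (n species, total-carbon range, n oxidized)
_LIPID_UNIVERSE: dict[str, tuple[int, tuple[int, int], int]] = {
    "TAG": (90, (40, 66), 10),
    "DAG": (40, (28, 44), 0),
    "MAG": (8, (14, 22), 0),
    "PC": (70, (28, 44), 0),
    "LPC": (20, (14, 22), 0),
    "PE": (30, (28, 44), 0),
    "LPE": (8, (14, 22), 0),
    "PS": (16, (32, 44), 0),
    "PI": (16, (32, 44), 0),
    "PG": (8, (30, 40), 0),
    "SM": (24, (30, 44), 0),
    "Cer": (16, (32, 44), 0),
    "HexCer": (8, (34, 44), 0),
    "CE": (12, (14, 22), 0),
    "FA": (30, (12, 24), 6),
    "CAR": (20, (2, 20), 0),
}


def _lipid_species(c_range: tuple[int, int], n_species: int) -> list[tuple[int, int]]:
    """Distinct (total carbons, total double bonds) pairs spread over the
    class's grid, saturated through PUFA-enriched, deterministically."""
    c_lo, c_hi = c_range
    grid = [(c, d)
            for c in range(c_lo, c_hi + 1, 2)
            for d in range(max(1, min(12, c // 5)) + 1)]
    if n_species >= len(grid):
        return grid
    stride = len(grid) / n_species
    return [grid[int(i * stride)] for i in range(n_species)]


def nonlipid_lookup() -> dict[str, tuple[str, str]]:
    """lowercase name -> (superclass, subclass) for the packaged universe."""
    out: dict[str, tuple[str, str]] = {}
    for (superclass, subclass), names in _NONLIPID_UNIVERSE.items():
        for n in names:
            out[n.lower()] = (superclass, subclass)
    return out


def default_compound_universe() -> pd.DataFrame:
    """Annotation table for the default synthetic universe (~600 compounds).

    Lipid species are laid out deterministically over each class's
    carbon range with double-bond counts spanning saturated through
    PUFA-enriched, including oxidized TAG/FA species.
    """
    compounds: list[tuple[str, str]] = []
    idx = 1
    for code, (n_species, c_range, n_ox) in _LIPID_UNIVERSE.items():
        for k, (carbons, db) in enumerate(_lipid_species(c_range, n_species)):
            mods = ";O" if k < n_ox else ""
            name = f"{code} {carbons}:{db}{mods}"
            compounds.append((f"C{idx:04d}", name))
            idx += 1
    for (_superclass, _subclass), names in _NONLIPID_UNIVERSE.items():
        for n in names:
            compounds.append((f"C{idx:04d}", n))
            idx += 1
    return build_annotation_table(compounds, lookup=nonlipid_lookup())


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _make_metadata(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for sex in config.sexes:
        arms = [(design.CONTROL_LABEL, 0.0, config.n_control[sex])]
        for label, pct in design.GROUP_ORDER[sex]:
            if label != design.CONTROL_LABEL:
                arms.append((label, pct, config.n_per_treatment))
        arms.append((design.YOUNG_LABEL, 0.0, config.n_young))
        for label, pct, n in arms:
            for i in range(n):
                mouse = f"{sex[0].upper()}_{label}_{i + 1:02d}"
                for organ in config.organs:
                    rows.append({
                        "sample_id": f"{mouse}__{organ.replace(' ', '_')}",
                        "mouse_id": mouse, "sex": sex, "organ": organ,
                        "group": label, "lifespan_pct": pct,
                    })
    return pd.DataFrame(rows, columns=["sample_id", "mouse_id", "sex", "organ",
                                       "group", "lifespan_pct"])


def _class_offsets(subclasses: Sequence[str]) -> dict[str, float]:
    # deterministic per-subclass abundance offsets, independent of the seed
    uniq = sorted(set(subclasses))
    return {s: 2.0 * np.sin(3.7 * i) for i, s in enumerate(uniq)}


def generate(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Draw a full synthetic dataset plus its ground-truth ledger.

    Same seed, same config -> byte-identical tables. The ledger lists
    every (compound, organ, sex) with its injected beta and direction
    ("none" for beta = 0), so calibration and power are measurable
    against a known truth.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    ann = config.compounds if config.compounds is not None else default_compound_universe()
    metadata = _make_metadata(config)
    compound_ids = list(ann["compound_id"])
    subclass = dict(zip(ann["compound_id"], ann["subclass"]))
    # amino-acid subclasses live in the annotation 'subclass' for non-lipids
    offsets = _class_offsets(list(subclass.values()))

    # beta[(organ, sex)] -> vector over compounds
    beta: dict[tuple[str, str], np.ndarray] = {}
    for organ in config.organs:
        for sex in config.sexes:
            b = np.zeros(len(compound_ids))
            for eff in config.trend_spec:
                mask = np.array([
                    eff.selects(cid, subclass[cid], organ, sex)
                    for cid in compound_ids])
                b[mask] = eff.beta
            beta[(organ, sex)] = b

    base = np.array([config.baseline_log_mean + offsets[subclass[cid]]
                     for cid in compound_ids])

    n_samples = len(metadata)
    log_mean = np.empty((n_samples, len(compound_ids)))
    for row_i, row in enumerate(metadata.itertuples(index=False)):
        b = beta[(row.organ, row.sex)]
        mean = base + b * row.lifespan_pct
        if row.group == design.YOUNG_LABEL and config.young_mimic:
            cr_pct = design.lifespan_pct(row.sex, "CR")
            mean = base + b * cr_pct
        log_mean[row_i] = mean

    log_int = log_mean + rng.normal(0.0, config.noise_sd, size=log_mean.shape)
    intensities = np.power(10.0, log_int)
    if config.missing_rate > 0:
        miss = rng.random(intensities.shape) < config.missing_rate
        intensities[miss] = np.nan

    features = pd.DataFrame(intensities, index=metadata["sample_id"],
                            columns=compound_ids)

    truth_rows = []
    for organ in config.organs:
        for sex in config.sexes:
            b = beta[(organ, sex)]
            for cid, bb in zip(compound_ids, b):
                truth_rows.append({
                    "compound_id": cid, "organ": organ, "sex": sex,
                    "beta": bb,
                    "direction": "up" if bb > 0 else ("down" if bb < 0 else "none"),
                })
    truth = pd.DataFrame(truth_rows, columns=["compound_id", "organ", "sex",
                                              "beta", "direction"])
    return SyntheticDataset(features=features, metadata=metadata,
                            annotations=ann, truth=truth)


def worked_example_fixture() -> SyntheticDataset:
    """Tiny hand-checkable dataset: 3 ordered groups x 2 samples x 6 compounds.

    "trend_perfect" carries the maximal-trend values [1,2],[3,4],[5,6]
    (J = 12, exact one-sided p = 1/90); "flat" is constant (p = 1);
    "TAG 58:8" lands in the (very_long, pufa_enriched) bins.
    """
    groups = [("G1", 0.0), ("G2", 10.0), ("G3", 20.0)]
    rows = []
    for label, pct in groups:
        for i in (1, 2):
            rows.append({"sample_id": f"{label}_s{i}", "mouse_id": f"{label}_m{i}",
                         "sex": "male", "organ": "plasma", "group": label,
                         "lifespan_pct": pct})
    metadata = pd.DataFrame(rows)
    values = {
        "trend_perfect": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "trend_down": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
        "flat": [7.0] * 6,
        "TAG 58:8": [10.0, 12.0, 30.0, 32.0, 55.0, 60.0],
        "PC 34:1": [9.0, 11.0, 10.0, 12.0, 9.5, 10.5],
        "glycylglycine": [5.0, 6.0, 4.0, 7.0, 5.5, 6.5],
    }
    features = pd.DataFrame(values, index=metadata["sample_id"])
    names = list(values)
    annotations = build_annotation_table(
        [(n, n) for n in names], lookup=nonlipid_lookup())
    # opaque ids double as names here; trend_perfect/trend_down/flat are
    # deliberately unclassifiable plumbing compounds
    truth = pd.DataFrame(
        [{"compound_id": "trend_perfect", "organ": "plasma", "sex": "male",
          "beta": 1.0, "direction": "up"},
         {"compound_id": "trend_down", "organ": "plasma", "sex": "male",
          "beta": -1.0, "direction": "down"},
         {"compound_id": "flat", "organ": "plasma", "sex": "male",
          "beta": 0.0, "direction": "none"}],
        columns=["compound_id", "organ", "sex", "beta", "direction"])
    return SyntheticDataset(features=features, metadata=metadata,
                            annotations=annotations, truth=truth)
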