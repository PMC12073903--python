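"""Study-design constants: intervention orderings and organ panel.

The six-group design compares a 12-month-old control arm against five
lifespan-extending interventions (17-alpha-estradiol, canagliflozin,
acarbose, rapamycin, caloric restriction), with an additional 4-month-old
"Young" reference arm. Reported average lifespan-extension percentages
differ by sex, which changes the intervention ordering used by the trend
test: the trend statistic only consumes the ordering, never the
percentages themselves.
"""

from __future__ import annotations

# (label, lifespan-extension percent), in increasing order of effect.
FEMALE_GROUPS: tuple[tuple[str, float], ...] = (
    ("Control", 0.0),
    ("17aE2", 1.0),
    ("Cana", 1.0),
    ("Aca", 5.0),
    ("Rapa", 21.0),
    ("CR", 40.0),
)

MALE_GROUPS: tuple[tuple[str, float], ...] = (
    ("Control", 0.0),
    ("Rapa", 13.0),
    ("Cana", 14.0),
    ("17aE2", 19.0),
    ("Aca", 22.0),
    ("CR", 33.0),
)

GROUP_ORDER: dict[str, tuple[tuple[str, float], ...]] = {
    "female": FEMALE_GROUPS,
    "male": MALE_GROUPS,
}

TREATMENTS: tuple[str, ...] = ("17aE2", "Cana", "Aca", "Rapa", "CR")

CONTROL_LABEL = "Control"
YOUNG_LABEL = "Young"

SEXES: tuple[str, ...] = ("female", "male")

ORGANS: tuple[str, ...] = (
    "plasma",
    "liver",
    "gastrocnemius muscle",
    "kidney",
    "gonadal fat",
    "inguinal fat",
)


def lifespan_pct(sex: str, label: str) -> float:
    """Lifespan-extension percent for a treatment label in a given sex."""
    for lab, pct in GROUP_ORDER[sex]:
        if lab == label:
            return pct
    raise KeyError(f"unknown group label {label!r} for sex {sex!r}")


def ordered_labels(sex: str) -> list[str]:
    """Group labels in increasing order of lifespan-extension effect."""
    return [lab for lab, _ in GROUP_ORDER[sex]]
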