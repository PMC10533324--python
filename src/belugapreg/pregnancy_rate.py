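"""Population pregnancy rate with colour-class maturity correction.

A blind biopsy sample contains females of unknown sexual maturity, and
an immature female in the denominator biases the pregnancy rate down.
Skin colour (grey -> off-white -> white with age) is an imperfect
maturity proxy; necropsy series give per-colour-class maturity
probabilities (here 100% white, 100% off-white, 10% grey). The
correction distributes the non-pregnant females of unknown maturity
according to those probabilities and adds the expected number of matures
to the denominator:

    adjusted rate = n_pregnant / (min_mature + round(sum_c count_c * p_c))

where ``min_mature`` counts females that are demonstrably mature —
presumed pregnant, intermediate-cluster, and lactating (including
'virtual biopsies': females flanked by a newborn calf that would have
been darted, recorded as lactating to avoid a capturability bias).
With a three-year reproductive cycle, one third of mature females are
expected to enter gestation each year, which gives the expected pregnant
count the observed rate is compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "MaturitySchedule",
    "ColourCounts",
    "PregnancyRateEstimate",
    "expected_mature_count",
    "expected_pregnant_count",
    "adjusted_pregnancy_rate",
    "round_half_away",
    "DEFAULT_SCHEDULE",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (so 10.5 -> 11)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class MaturitySchedule:
    """Colour class -> probability of sexual maturity, plus cycle fraction."""

    probabilities: dict
    cycle_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for cls, p in self.probabilities.items():
            if not 0 <= p <= 1:
                raise ValueError(f"maturity probability for {cls!r} outside [0, 1]")
        if not 0 < self.cycle_fraction <= 1:
            raise ValueError("cycle_fraction must be in (0, 1]")

    def probability(self, colour_class: str) -> float:
        try:
            return self.probabilities[colour_class]
        except KeyError:
            raise ValueError(
                f"colour class {colour_class!r} missing from maturity schedule"
            ) from None


#: Necropsy-derived maturity rates for females aged 3+ (white 75/75,
#: off-white 4/4, grey 1/10) and the one-calf-every-three-years cycle.
DEFAULT_SCHEDULE = MaturitySchedule(
    probabilities={"white": 1.0, "off-white": 1.0, "grey": 0.1},
    cycle_fraction=1.0 / 3.0,
)


@dataclass(frozen=True)
class ColourCounts:
    """Per colour class: (biopsied count, virtual-biopsy count)."""

    counts: dict  # colour class -> (biopsied, virtual)

    def __post_init__(self) -> None:
        for cls, (b, v) in self.counts.items():
            if b < 0 or v < 0:
                raise ValueError(f"negative count for colour class {cls!r}")


@dataclass
class PregnancyRateEstimate:
    n_pregnant: int
    min_mature: int
    additional_mature: int
    raw_rate: float
    adjusted_rate: float
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def adjusted_denominator(self) -> int:
        return self.min_mature + self.additional_mature


def expected_mature_count(
    counts: ColourCounts, schedule: MaturitySchedule
) -> tuple[float, int, pd.DataFrame]:
    """Expected number of mature females in a colour-classified sample.

    Biopsied counts are weighted by the class maturity probability;
    virtual biopsies are lactating females, hence mature with probability
    one. Returns (unrounded sum, rounded count, per-class audit).
    """
    rows = []
    for cls, (biopsied, virtual) in counts.counts.items():
        p = schedule.probability(cls)
        rows.append(
            {
                "colour_class": cls,
                "biopsied": biopsied,
                "virtual": virtual,
                "maturity_probability": p,
                "expected_mature": biopsied * p + virtual,
            }
        )
    audit = pd.DataFrame(rows)
    total = float(audit["expected_mature"].sum()) if rows else 0.0
    return total, round_half_away(total), audit


def expected_pregnant_count(mature: float, cycle_fraction: float = 1.0 / 3.0) -> int:
    """Expected pregnancies per year among ``mature`` females."""
    if mature < 0:
        raise ValueError("mature count must be >= 0")
    return round_half_away(mature * cycle_fraction)


def adjusted_pregnancy_rate(
    n_pregnant: int,
    min_mature: int,
    nonpregnant_colour_counts: dict,
    schedule: MaturitySchedule,
) -> PregnancyRateEstimate:
    """Maturity-corrected pregnancy rate.

    ``min_mature`` is the demonstrably mature denominator; the colour
    counts of non-pregnant females of unknown maturity contribute an
    expected ``round(sum count_c * p_c)`` additional matures.
    """
    if min_mature <= 0:
        raise ValueError("min_mature must be > 0 (zero denominator)")
    if n_pregnant > min_mature:
        raise ValueError("n_pregnant cannot exceed the minimum mature count")
    rows = []
    for cls, count in nonpregnant_colour_counts.items():
        if count < 0:
            raise ValueError(f"negative count for colour class {cls!r}")
        p = schedule.probability(cls)
        rows.append(
            {
                "colour_class": cls,
                "nonpregnant_unknown_maturity": count,
                "maturity_probability": p,
                "expected_additional_mature": count * p,
            }
        )
    audit = pd.DataFrame(rows)
    additional = (
        round_half_away(float(audit["expected_additional_mature"].sum()))
        if rows
        else 0
    )
    return PregnancyRateEstimate(
        n_pregnant=int(n_pregnant),
        min_mature=int(min_mature),
        additional_mature=additional,
        raw_rate=n_pregnant / min_mature,
        adjusted_rate=n_pregnant / (min_mature + additional),
        audit=audit,
    )
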