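"""Fixed-threshold classification and empirical gap detection.

The simplest of the three classifiers: a single concentration cutoff read
off a visible break in the BP frequency distribution (100 ng g^-1 tissue;
around 150 ng g^-1 on the per-lipid metric). A value exactly at the
threshold classifies as pregnant (inclusive-above convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThresholdRule",
    "classify_fixed_threshold",
    "find_gap",
    "PREGNANT",
    "NON_PREGNANT",
]

PREGNANT = "pregnant"
NON_PREGNANT = "non-pregnant"

#: Default thresholds per unit metric, ng g^-1.
DEFAULT_THRESHOLDS = {"tissue": 100.0, "lipid": 150.0}


@dataclass(frozen=True)
class ThresholdRule:
    """A fixed cutoff on one unit metric (``tissue`` or ``lipid``)."""

    threshold: float = 100.0
    unit_metric: str = "tissue"
    inclusive_above: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.unit_metric not in ("tissue", "lipid"):
            raise ValueError("unit_metric must be 'tissue' or 'lipid'")


def classify_fixed_threshold(values, rule: ThresholdRule, values_unit: str | None = None):
    """Label each BP value pregnant / non-pregnant against a fixed cutoff.

    ``values_unit``, if given, must match ``rule.unit_metric``; comparing
    per-tissue values against a per-lipid threshold is a unit error.
    """
    if values_unit is not None and values_unit != rule.unit_metric:
        raise ValueError(
            f"values are per {values_unit} but rule is per {rule.unit_metric}"
        )
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("BP values must be >= 0")
    if rule.inclusive_above:
        preg = values >= rule.threshold
    else:
        preg = values > rule.threshold
    return np.where(preg, PREGNANT, NON_PREGNANT)


def find_gap(values, window: tuple[float, float] = (1.0, 1000.0)) -> tuple[float, float]:
    """Widest empty interval between consecutive order statistics.

    Returns ``(lower, upper)`` with no observation strictly inside, taking
    the maximum of ``upper - lower`` over consecutive distinct sorted values
    whose endpoints both fall inside ``window``. The window keeps the
    trivially enormous gap above the sample maximum from being returned.
    """
    distinct = np.unique(np.asarray(values, dtype=float))
    if distinct.size < 2:
        raise ValueError("find_gap requires at least 2 distinct values")
    lo, hi = window
    inside = distinct[(distinct >= lo) & (distinct <= hi)]
    candidates = inside if inside.size >= 2 else distinct
    diffs = np.diff(candidates)
    i = int(np.argmax(diffs))
    return float(candidates[i]), float(candidates[i + 1])
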