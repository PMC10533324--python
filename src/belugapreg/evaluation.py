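"""Scoring classifications against known reproductive status.

Adjudication: the hormone signal of a pregnancy that ended days to weeks
before sampling is still expected in blubber, so recently parturient
females are scored as expected-pregnant alongside confirmed pregnancies;
males, lactating, immature and resting females are expected-non-pregnant.
When a three-cluster classifier must be compared on a dichotomy, the
'intermediate' cluster scores as non-pregnant (it is excluded from the
pregnant numerator but kept in the mature denominator downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "expected_label",
    "misclassification_count",
    "unit_switch_fraction",
    "MisclassificationReport",
    "SwitchReport",
    "EXPECTED_LABELS",
]

EXPECTED_LABELS = {
    "pregnant": "pregnant",
    "recent_parturition": "pregnant",
    "lactating": "non-pregnant",
    "resting": "non-pregnant",
    "immature_female": "non-pregnant",
    "immature_male": "non-pregnant",
    "mature_male": "non-pregnant",
}


def expected_label(status: str) -> str:
    """Expected dichotomous label for one known reproductive status."""
    try:
        return EXPECTED_LABELS[status]
    except KeyError:
        raise ValueError(
            f"cannot adjudicate status {status!r}: evaluation requires known truth"
        ) from None


def _dichotomize(labels) -> np.ndarray:
    lab = np.asarray(labels, dtype=object)
    return np.where(lab == "intermediate", "non-pregnant", lab)


@dataclass
class MisclassificationReport:
    count: int
    n: int
    by_status: pd.DataFrame  # per true status: n, errors


def misclassification_count(
    predicted, expected, statuses=None
) -> MisclassificationReport:
    """Count disagreements between predicted and expected labels.

    'intermediate' predictions score as non-pregnant. If per-sample true
    ``statuses`` are supplied, a per-status error breakdown is included.
    """
    pred = _dichotomize(predicted)
    exp = _dichotomize(expected)
    if pred.shape != exp.shape:
        raise ValueError(
            f"length mismatch: {pred.shape[0]} predicted vs {exp.shape[0]} expected"
        )
    errors = pred != exp
    if statuses is not None:
        statuses = np.asarray(statuses, dtype=object)
        if statuses.shape != pred.shape:
            raise ValueError("statuses must align with the labels")
        by = (
            pd.DataFrame({"status": statuses, "error": errors})
            .groupby("status", sort=True)["error"]
            .agg(n="size", errors="sum")
            .reset_index()
        )
    else:
        by = pd.DataFrame(columns=["status", "n", "errors"])
    return MisclassificationReport(count=int(errors.sum()), n=len(pred), by_status=by)


@dataclass
class SwitchReport:
    fraction: float
    n: int
    switched: np.ndarray  # per-sample flags
    table: pd.DataFrame  # switch flag joined to lipid fraction


def unit_switch_fraction(
    labels_tissue, labels_lipid, lipid_fractions=None
) -> SwitchReport:
    """Fraction of samples whose assignment changes between unit metrics.

    Joins the per-sample switch flag to lipid fractions when given, since
    switching concentrates in low-lipid samples.
    """
    t = np.asarray(labels_tissue, dtype=object)
    l = np.asarray(labels_lipid, dtype=object)
    if t.shape != l.shape:
        raise ValueError(
            f"misaligned label sets: {t.shape[0]} per-tissue vs {l.shape[0]} per-lipid"
        )
    switched = t != l
    if lipid_fractions is not None:
        lf = np.asarray(lipid_fractions, dtype=float)
        if lf.shape != t.shape:
            raise ValueError("lipid_fractions must align with the labels")
        table = pd.DataFrame({"switched": switched, "lipid_fraction": lf})
    else:
        table = pd.DataFrame({"switched": switched})
    frac = float(switched.mean()) if len(t) else 0.0
    return SwitchReport(fraction=frac, n=len(t), switched=switched, table=table)
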