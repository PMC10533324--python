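"""Concentration units: assay back-calculation, lipid metric, filters.

Raw competitive-ELISA readings come back in pg mL^-1 of assay buffer. The
back-calculation to ng per g of blubber tissue is the standard one:

    bp_tissue = (raw * buffer_volume * dilution / 1000) / (recovery * mass)

with the division by 1000 converting pg to ng, and the recovery fraction
(extraction efficiency, e.g. 0.883 for carcass batches, 0.710 for biopsy
batches) dividing out the hormone lost during extraction. Dilution and
recovery corrections are multiplicative, hence commute.

The per-lipid metric divides the tissue concentration by the lipid mass
fraction of the sample; carcass samples without a measured lipid content
are imputed with the mean of the measured carcasses (66.4%). Biopsy
samples at or below a low-lipid cutoff (default 5%) are excluded because
tiny lipid denominators make the per-lipid metric explode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AssayRecord",
    "adjust_assay_concentration",
    "tissue_to_lipid",
    "impute_lipid_fraction",
    "filter_low_lipid",
    "log_bp",
    "floor_detection_limit",
    "DEFAULT_CARCASS_LIPID",
    "DEFAULT_LOW_LIPID_CUTOFF",
    "DEFAULT_DETECTION_LIMIT",
]

#: Mean lipid fraction of the measured carcass subsample, used as fallback.
DEFAULT_CARCASS_LIPID = 0.664
#: Biopsies at or below this lipid fraction are excluded (boundary inclusive).
DEFAULT_LOW_LIPID_CUTOFF = 0.05
#: Smallest observed tissue concentration; optional floor for non-positives.
DEFAULT_DETECTION_LIMIT = 0.1


@dataclass(frozen=True)
class AssayRecord:
    """One raw immunoassay measurement with its back-calculation factors.

    Parameters
    ----------
    raw_concentration : float
        Plate reading in pg mL^-1 of assay buffer.
    blubber_mass : float
        Wet mass of the extracted blubber subsample, g.
    buffer_volume : float
        Resuspension volume in mL (extract taken up in 500 uL of buffer).
    dilution_factor : float
        >= 1; applied when the reading fell outside the standard curve.
    recovery_fraction : float
        Extraction efficiency in (0, 1].
    """

    raw_concentration: float
    blubber_mass: float
    buffer_volume: float = 0.5
    dilution_factor: float = 1.0
    recovery_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.raw_concentration < 0:
            raise ValueError("raw_concentration must be >= 0")
        if self.blubber_mass <= 0:
            raise ValueError("blubber_mass must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if not 0 < self.recovery_fraction <= 1:
            raise ValueError("recovery_fraction must be in (0, 1]")
        if self.buffer_volume <= 0:
            raise ValueError("buffer_volume must be > 0")


def adjust_assay_concentration(record: AssayRecord) -> float:
    """Back-calculate ng progesterone per g blubber tissue from a plate read."""
    total_ng = (
        record.raw_concentration * record.buffer_volume * record.dilution_factor
    ) / 1000.0
    return total_ng / (record.recovery_fraction * record.blubber_mass)


def tissue_to_lipid(bp_tissue, lipid_fraction):
    """Convert ng g^-1 tissue to ng g^-1 lipid by dividing by lipid fraction."""
    bp_tissue = np.asarray(bp_tissue, dtype=float)
    lipid_fraction = np.asarray(lipid_fraction, dtype=float)
    if np.any(lipid_fraction <= 0) or np.any(lipid_fraction > 1):
        raise ValueError("lipid_fraction must be in (0, 1]")
    out = bp_tissue / lipid_fraction
    return float(out) if out.ndim == 0 else out


def impute_lipid_fraction(
    samples: pd.DataFrame, fallback: float = DEFAULT_CARCASS_LIPID
) -> pd.DataFrame:
    """Fill missing lipid fractions with ``fallback`` and flag the rows.

    Present values are untouched; ``bp_lipid_ng_g`` is (re)derived for the
    imputed rows from the tissue concentration.
    """
    if not 0 < fallback <= 1:
        raise ValueError("fallback must be in (0, 1]")
    out = samples.copy()
    missing = out["lipid_fraction"].isna()
    out.loc[missing, "lipid_fraction"] = fallback
    out["lipid_imputed"] = missing | out.get("lipid_imputed", False)
    fill = missing & out["bp_tissue_ng_g"].notna()
    out.loc[fill, "bp_lipid_ng_g"] = (
        out.loc[fill, "bp_tissue_ng_g"] / out.loc[fill, "lipid_fraction"]
    )
    return out


def filter_low_lipid(
    samples: pd.DataFrame, min_fraction: float = DEFAULT_LOW_LIPID_CUTOFF
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into (retained, excluded) at lipid_fraction <= min_fraction.

    The boundary is inclusive on the excluded side. Rows with no lipid value
    are retained (nothing to test against). The partition is exhaustive and
    disjoint.
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    low = samples["lipid_fraction"].notna() & (
        samples["lipid_fraction"] <= min_fraction
    )
    return samples.loc[~low].copy(), samples.loc[low].copy()


def log_bp(values):
    """Natural log of BP concentrations; rejects non-positive values."""
    values = np.asarray(values, dtype=float)
    if np.any(~(values > 0)):
        raise ValueError(
            "BP values must be > 0 for log transform; floor non-detects at "
            "the detection limit first (floor_detection_limit)"
        )
    out = np.log(values)
    return float(out) if out.ndim == 0 else out


def floor_detection_limit(values, limit: float = DEFAULT_DETECTION_LIMIT):
    """Raise values below ``limit`` (e.g. assay non-detects) up to it."""
    if limit <= 0:
        raise ValueError("limit must be > 0")
    out = np.maximum(np.asarray(values, dtype=float), limit)
    return float(out) if out.ndim == 0 else out
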