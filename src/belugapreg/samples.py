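"""Canonical sample table schema and CSV round-trip I/O.

One row per individual. Concentrations are blubber progesterone (BP) in
ng per g of tissue and (where lipid content is known or imputed) ng per g
of extracted lipid. ``latent_truth`` is only ever written by the synthetic
generator and is never consumed by any classifier; it exists so recovery
tests can compare assignments against the generating component.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA_COLUMNS",
    "PROGRAMS",
    "SEXES",
    "COLOUR_CLASSES",
    "STATUSES",
    "CLASSIFIER_COLUMNS",
    "read_samples",
    "write_samples",
    "validate_samples",
]

SCHEMA_COLUMNS = [
    "sample_id",
    "program",
    "sex",
    "colour_class",
    "status",
    "bp_tissue_ng_g",
    "bp_lipid_ng_g",
    "lipid_fraction",
    "lipid_imputed",
    "is_virtual",
    "latent_truth",
]

PROGRAMS = {"SLE_carcass", "NUN_carcass", "SLE_biopsy", "virtual_biopsy"}
SEXES = {"female", "male"}
COLOUR_CLASSES = {"grey", "off-white", "white"}
STATUSES = {
    "pregnant",
    "recent_parturition",
    "lactating",
    "resting",
    "immature_female",
    "immature_male",
    "mature_male",
    "unknown",
}

#: Columns a classifier is allowed to consume (schema-level firewall: the
#: latent generating label must never leak into these).
CLASSIFIER_COLUMNS = [
    "sample_id",
    "program",
    "sex",
    "colour_class",
    "status",
    "bp_tissue_ng_g",
    "bp_lipid_ng_g",
    "lipid_fraction",
    "lipid_imputed",
    "is_virtual",
]

_BOOL_COLUMNS = ("lipid_imputed", "is_virtual")
_FLOAT_COLUMNS = ("bp_tissue_ng_g", "bp_lipid_ng_g", "lipid_fraction")


def _rows(mask: pd.Series) -> str:
    return ", ".join(str(i) for i in mask[mask].index.tolist())


def validate_samples(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` naming offending rows on any schema violation."""
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns and c != "latent_truth"]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    dup = df["sample_id"].duplicated(keep=False)
    if dup.any():
        raise ValueError(f"duplicate sample_id at rows: {_rows(dup)}")
    for col, allowed in (
        ("program", PROGRAMS),
        ("sex", SEXES),
        ("colour_class", COLOUR_CLASSES),
        ("status", STATUSES),
    ):
        values = df[col].dropna()
        bad = ~values.isin(allowed)
        if bad.any():
            raise ValueError(
                f"unknown {col} value(s) {sorted(values[bad].unique())} "
                f"at rows: {_rows(bad)}"
            )
    for col in ("bp_tissue_ng_g", "bp_lipid_ng_g"):
        if col in df.columns:
            neg = df[col].astype(float) < 0
            if neg.fillna(False).any():
                raise ValueError(f"negative {col} at rows: {_rows(neg.fillna(False))}")
    if "lipid_fraction" in df.columns:
        lf = df["lipid_fraction"].astype(float)
        bad = (lf <= 0) | (lf > 1)
        if bad.fillna(False).any():
            raise ValueError(
                f"lipid_fraction outside (0, 1] at rows: {_rows(bad.fillna(False))}"
            )


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "latent_truth" not in df.columns:
        df["latent_truth"] = pd.Series([pd.NA] * len(df), dtype="object")
    for col in _FLOAT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    for col in _BOOL_COLUMNS:
        if df[col].dtype == object:
            df[col] = df[col].map(
                {"True": True, "False": False, True: True, False: False}
            )
        df[col] = df[col].fillna(False).astype(bool)
    for col in ("sample_id", "program", "sex", "colour_class", "status", "latent_truth"):
        df[col] = df[col].astype("object")
        df.loc[df[col].isna(), col] = pd.NA
    return df[SCHEMA_COLUMNS]


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read and validate a canonical sample CSV (UTF-8, header mandatory)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=True, encoding="utf-8")
    if len(df) == 0 and list(df.columns) == []:
        raise ValueError(f"{path}: header line is mandatory")
    df = _coerce(df)
    validate_samples(df)
    return df


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a canonical sample CSV; round-trips exactly."""
    df = _coerce(df)
    validate_samples(df)
    out = df.copy()
    for col in _BOOL_COLUMNS:
        out[col] = np.where(out[col], "True", "False")
    out.to_csv(path, index=False, encoding="utf-8")
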