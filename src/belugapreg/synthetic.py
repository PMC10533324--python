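"""Synthetic sample tables with the statistical structure of the study.

Per reproductive-status group, blubber progesterone is drawn from a
lognormal whose raw-scale mean m and SD s are moment-matched:

    sigma^2 = ln(1 + s^2 / m^2),    mu = ln(m) - sigma^2 / 2.

The published group statistics are raw-scale means and SDs while all
analyses run on natural-log values; the lognormal is the minimal
distribution consistent with both and is an implementation choice, not a
claim about the real within-group law. Lipid fractions come from a
moment-matched Beta truncated away from 0 so per-lipid concentrations
stay finite. The latent generating component of an unknown-population
draw is stored only in ``latent_truth`` — a column no classifier reads —
so recovery tests can score assignments without leaking truth.

All randomness flows from a single seed through counter-based stream
splitting, so fixed seeds give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import spawn_rng
from .samples import SCHEMA_COLUMNS

__all__ = [
    "GroupSpec",
    "PopulationSpec",
    "lognormal_params",
    "simulate_known_samples",
    "simulate_unknown_population",
    "simulate_lipid_fractions",
    "KNOWN_STATUS_GROUPS",
    "biopsy_population",
    "nunavik_population",
]

_STATUS_SEX = {
    "immature_male": "male",
    "mature_male": "male",
}

_MIN_LIPID = 1e-3  # truncation keeping per-lipid units finite


@dataclass(frozen=True)
class GroupSpec:
    """One reproductive-status group: count and raw-scale BP moments (ng/g)."""

    status: str
    n: int
    mean_raw: float
    sd_raw: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"group {self.status!r}: n must be >= 0")
        if self.mean_raw <= 0:
            raise ValueError(f"group {self.status!r}: mean_raw must be > 0")
        if self.sd_raw < 0:
            raise ValueError(f"group {self.status!r}: sd_raw must be >= 0")


#: The seven known-status carcass groups (sample size, raw mean, raw SD).
KNOWN_STATUS_GROUPS = [
    GroupSpec("immature_male", 6, 1.1, 1.3),
    GroupSpec("mature_male", 5, 0.8, 0.7),
    GroupSpec("immature_female", 4, 0.6, 0.5),
    GroupSpec("resting", 7, 3.1, 4.5),
    GroupSpec("pregnant", 13, 365.0, 244.0),
    GroupSpec("recent_parturition", 10, 273.0, 227.0),
    GroupSpec("lactating", 17, 38.4, 100.0),
]


@dataclass(frozen=True)
class PopulationSpec:
    """A mixture population of unknown-status individuals.

    ``weights`` are per-component mixing proportions over ``components``;
    lipid fractions are Beta(lipid_mean, lipid_sd); colour classes are
    drawn from ``colour_proportions``.
    """

    weights: tuple
    components: tuple
    lipid_mean: float = 0.243
    lipid_sd: float = 0.15
    colour_proportions: dict = field(
        default_factory=lambda: {"white": 30 / 51, "off-white": 9 / 51, "grey": 12 / 51}
    )
    program: str = "SLE_biopsy"

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.components):
            raise ValueError("weights and components must align")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if not 0 < self.lipid_mean <= 1:
            raise ValueError("lipid_mean must be in (0, 1]")
        if abs(sum(self.colour_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("colour proportions must sum to 1")


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of the lognormal matching raw mean and SD."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2), float(np.sqrt(sigma2))


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in SCHEMA_COLUMNS})


def simulate_known_samples(
    specs: list[GroupSpec], seed: int, program: str = "SLE_carcass"
) -> pd.DataFrame:
    """Draw a known-status sample table, one lognormal per group spec.

    With sd_raw 0 the group is degenerate at its mean. Lipid fraction is
    left missing (carcass lipid content is mostly unmeasured and imputed
    downstream). Deterministic under a fixed seed.
    """
    if not specs:
        return _empty_table()
    frames = []
    for g_idx, spec in enumerate(specs):
        rng = spawn_rng(seed, "known", g_idx)
        if spec.sd_raw == 0:
            bp = np.full(spec.n, spec.mean_raw)
        else:
            mu, sigma = lognormal_params(spec.mean_raw, spec.sd_raw)
            bp = rng.lognormal(mu, sigma, size=spec.n)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": [f"{program}_{spec.status}_{i:04d}" for i in range(spec.n)],
                    "program": program,
                    "sex": _STATUS_SEX.get(spec.status, "female"),
                    "colour_class": "white"
                    if not spec.status.startswith("immature")
                    else "grey",
                    "status": spec.status,
                    "bp_tissue_ng_g": bp,
                    "bp_lipid_ng_g": np.nan,
                    "lipid_fraction": np.nan,
                    "lipid_imputed": False,
                    "is_virtual": False,
                    "latent_truth": pd.NA,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[SCHEMA_COLUMNS]


def simulate_lipid_fractions(mean: float, sd: float, n: int, seed: int) -> np.ndarray:
    """Moment-matched Beta draws of lipid mass fraction, in (0, 1]."""
    if not 0 < mean < 1:
        raise ValueError("mean must be inside (0, 1)")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n < 0:
        raise ValueError("n must be >= 0")
    if sd == 0:
        return np.full(n, mean)
    var = sd**2
    if var >= mean * (1 - mean):
        raise ValueError(
            f"no Beta on (0,1) has mean {mean} and sd {sd}; "
            f"need sd^2 < mean*(1-mean) = {mean * (1 - mean):.4g}"
        )
    nu = mean * (1 - mean) / var - 1
    rng = spawn_rng(seed, "lipid")
    return np.maximum(rng.beta(mean * nu, (1 - mean) * nu, size=n), _MIN_LIPID)


def simulate_unknown_population(
    spec: PopulationSpec, n: int, seed: int
) -> pd.DataFrame:
    """Draw ``n`` unknown-status females from a mixture population.

    Each record carries the BP value (both units), a lipid fraction, a
    colour class, and the latent generating component name in
    ``latent_truth`` (never read by classifiers).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return _empty_table()
    rng = spawn_rng(seed, "unknown")
    comp = rng.choice(len(spec.components), size=n, p=np.asarray(spec.weights))
    bp = np.empty(n)
    for k, g in enumerate(spec.components):
        idx = comp == k
        m = int(idx.sum())
        if m == 0:
            continue
        if g.sd_raw == 0:
            bp[idx] = g.mean_raw
        else:
            mu, sigma = lognormal_params(g.mean_raw, g.sd_raw)
            bp[idx] = spawn_rng(seed, "unknown_bp", k).lognormal(mu, sigma, size=m)
    lipid = simulate_lipid_fractions(spec.lipid_mean, spec.lipid_sd, n, seed)
    colours = rng.choice(
        list(spec.colour_proportions), size=n, p=list(spec.colour_proportions.values())
    )
    return pd.DataFrame(
        {
            "sample_id": [f"{spec.program}_{i:04d}" for i in range(n)],
            "program": spec.program,
            "sex": "female",
            "colour_class": colours,
            "status": "unknown",
            "bp_tissue_ng_g": bp,
            "bp_lipid_ng_g": bp / lipid,
            "lipid_fraction": lipid,
            "lipid_imputed": False,
            "is_virtual": False,
            "latent_truth": [spec.components[k].status for k in comp],
        }
    )[SCHEMA_COLUMNS]


def biopsy_population() -> PopulationSpec:
    """Free-ranging biopsy-like population: three BP clusters, low lipid.

    Cluster moments are the per-tissue means/SDs of the three biopsy
    clusters (low 0.9 +/- 0.5, intermediate 33.6 +/- 21.3, high
    253 +/- 99 ng/g) with weights 20/23/22 over 65; lipid averages 24.3%.
    """
    return PopulationSpec(
        weights=(20 / 65, 23 / 65, 22 / 65),
        components=(
            GroupSpec("low", 0, 0.9, 0.5),
            GroupSpec("intermediate", 0, 33.6, 21.3),
            GroupSpec("pregnant", 0, 253.0, 99.0),
        ),
        lipid_mean=0.243,
        lipid_sd=0.15,
        program="SLE_biopsy",
    )


def nunavik_population() -> PopulationSpec:
    """Harvest-carcass-like population: two BP clusters, high lipid.

    Resting vs pregnant group moments with weights 0.54/0.46 (roughly 62-64
    of 135 harvested females classifying pregnant); lipid averages 60.9%.
    """
    return PopulationSpec(
        weights=(0.54, 0.46),
        components=(
            GroupSpec("resting", 0, 3.1, 4.5),
            GroupSpec("pregnant", 0, 365.0, 244.0),
        ),
        lipid_mean=0.609,
        lipid_sd=0.10,
        colour_proportions={"white": 0.7, "off-white": 0.15, "grey": 0.15},
        program="NUN_carcass",
    )
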