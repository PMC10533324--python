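"""End-to-end orchestration: preprocess, classify, evaluate, estimate.

Thin glue over the computational modules. Every stage draws its
randomness from the run seed through named stream splitting, outputs are
written only under the run's output directory, and a machine-readable
manifest (config + seed + versions) accompanies the results so a run is
reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import expected_label, misclassification_count
from .logistic import classify_by_probability, fit_logistic
from .mixture import MCMCSettings, fit_mixture, label_clusters, posterior_membership, select_mixture
from .pregnancy_rate import (
    DEFAULT_SCHEDULE,
    MaturitySchedule,
    PregnancyRateEstimate,
    adjusted_pregnancy_rate,
)
from .samples import read_samples, write_samples
from .threshold import DEFAULT_THRESHOLDS, ThresholdRule, classify_fixed_threshold
from .units import (
    DEFAULT_CARCASS_LIPID,
    DEFAULT_LOW_LIPID_CUTOFF,
    filter_low_lipid,
    impute_lipid_fraction,
)

__all__ = ["RunConfig", "run_pipeline", "preprocess", "rate_from_labels"]


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of one pipeline run."""

    input_path: str
    output_dir: str
    approaches: tuple = ("threshold", "mixture", "logistic")
    unit_metrics: tuple = ("tissue",)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    lipid_cutoff: float = DEFAULT_LOW_LIPID_CUTOFF
    lipid_fallback: float = DEFAULT_CARCASS_LIPID
    mixture_k: int | str = "auto"  # 1, 2, 3, or 'auto' (WAIC over 1-3)
    scaled_mcmc: bool = False
    maturity_schedule: MaturitySchedule = DEFAULT_SCHEDULE
    seed: int = 0

    def mcmc_settings(self) -> MCMCSettings:
        if self.scaled_mcmc:
            return MCMCSettings.scaled(seed=self.seed)
        return MCMCSettings(seed=self.seed)


def preprocess(samples: pd.DataFrame, config: RunConfig):
    """Impute carcass lipid, derive per-lipid BP, apply the low-lipid filter.

    Returns (retained, excluded, log entries). Only biopsy rows are
    subject to the low-lipid exclusion; carcass lipid is imputed with the
    measured-carcass mean.
    """
    log: list[str] = []
    carcass = samples["program"].isin(["SLE_carcass", "NUN_carcass"])
    missing = samples["lipid_fraction"].isna() & carcass
    out = samples.copy()
    if missing.any():
        imputed = impute_lipid_fraction(out.loc[carcass], fallback=config.lipid_fallback)
        out.loc[carcass, imputed.columns] = imputed
        log.append(f"imputed lipid_fraction={config.lipid_fallback} for {int(missing.sum())} carcass rows")
    derive = out["bp_lipid_ng_g"].isna() & out["lipid_fraction"].notna() & out["bp_tissue_ng_g"].notna()
    out.loc[derive, "bp_lipid_ng_g"] = (
        out.loc[derive, "bp_tissue_ng_g"] / out.loc[derive, "lipid_fraction"]
    )
    biopsy = out["program"] == "SLE_biopsy"
    keep_b, dropped = filter_low_lipid(out.loc[biopsy], config.lipid_cutoff)
    retained = pd.concat([out.loc[~biopsy], keep_b]).sort_index()
    log.append(
        f"excluded {len(dropped)} of {int(biopsy.sum())} biopsy rows with "
        f"lipid_fraction <= {config.lipid_cutoff}"
    )
    return retained, dropped, log


def _bp_column(unit: str) -> str:
    return {"tissue": "bp_tissue_ng_g", "lipid": "bp_lipid_ng_g"}[unit]


def rate_from_labels(
    labels: pd.Series,
    colour_classes: pd.Series,
    n_virtual: int,
    schedule: MaturitySchedule = DEFAULT_SCHEDULE,
) -> PregnancyRateEstimate:
    """Pregnancy-rate estimate from per-female cluster labels.

    The minimum mature denominator counts presumed-pregnant females,
    intermediate-cluster females, and the virtual (lactating) females;
    the remaining non-pregnant females of unknown maturity enter through
    the colour-class maturity correction.
    """
    labels = pd.Series(np.asarray(labels, dtype=object))
    n_pregnant = int((labels == "pregnant").sum())
    n_intermediate = int((labels == "intermediate").sum())
    min_mature = n_pregnant + n_intermediate + n_virtual
    nonpreg = labels == "non-pregnant"
    colour_counts = (
        pd.Series(np.asarray(colour_classes, dtype=object))[nonpreg.to_numpy()]
        .value_counts()
        .to_dict()
    )
    return adjusted_pregnancy_rate(n_pregnant, min_mature, colour_counts, schedule)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured approaches and write results + manifest.

    Returns a result bundle: per-approach/unit classification tables,
    evaluation reports on known-status rows, fitted model objects, and
    (when colour classes are present) a pregnancy-rate estimate.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = read_samples(config.input_path)
    data, excluded, log = preprocess(samples, config)
    real = data[~data["is_virtual"]]
    n_virtual = int(data["is_virtual"].sum())
    settings = config.mcmc_settings()

    results: dict = {"log": log, "excluded": excluded, "classifications": {}, "fits": {}}
    for unit in config.unit_metrics:
        col = _bp_column(unit)
        usable = real[real[col].notna() & (real[col] > 0)]
        table = usable[["sample_id", "program", "colour_class", "status", col]].copy()

        if "threshold" in config.approaches:
            rule = ThresholdRule(config.thresholds[unit], unit_metric=unit)
            table["label_threshold"] = classify_fixed_threshold(
                usable[col].to_numpy(), rule, values_unit=unit
            )
        if "mixture" in config.approaches:
            logv = np.log(usable[col].to_numpy(dtype=float))
            if config.mixture_k == "auto":
                fit, all_fits = select_mixture(logv, settings)
                results["fits"][f"mixture_{unit}_waic"] = {
                    k: f.waic for k, f in all_fits.items()
                }
            else:
                fit = fit_mixture(logv, int(config.mixture_k), settings)
            member = posterior_membership(fit, usable[col].to_numpy(dtype=float))
            names = label_clusters(fit) if fit.K > 1 else ["undifferentiated"]
            table["label_mixture"] = [names[i] for i in member.argmax(axis=1)]
            table["p_pregnant_mixture"] = member[:, fit.pregnant_cluster]
            results["fits"][f"mixture_{unit}"] = fit
        if "logistic" in config.approaches:
            known = usable[usable["status"] != "unknown"]
            unknown = usable[usable["status"] == "unknown"]
            fit, pred = fit_logistic(known, unknown, settings=settings, unit=unit)
            table["p_pregnant_logistic"] = np.nan
            table.loc[pred.index, "p_pregnant_logistic"] = pred["p_pregnant"].to_numpy()
            # individuals used in training get their coded label back
            trained = table["p_pregnant_logistic"].isna()
            table.loc[trained, "label_logistic"] = np.where(
                table.loc[trained, "status"] == "pregnant", "pregnant", "non-pregnant"
            )
            table.loc[~trained, "label_logistic"] = classify_by_probability(
                table.loc[~trained, "p_pregnant_logistic"].to_numpy()
            )
            results["fits"][f"logistic_{unit}"] = fit

        table.to_csv(outdir / f"classifications_{unit}.csv", index=False)
        results["classifications"][unit] = table

        # score approaches against known statuses where truth exists
        known_rows = table[table["status"] != "unknown"]
        if len(known_rows):
            evals = {}
            expected = known_rows["status"].map(expected_label).to_numpy()
            for approach in config.approaches:
                labcol = f"label_{approach}"
                if labcol in known_rows:
                    rep = misclassification_count(
                        known_rows[labcol].to_numpy(),
                        expected,
                        statuses=known_rows["status"].to_numpy(),
                    )
                    evals[approach] = rep
                    rep.by_status.to_csv(
                        outdir / f"evaluation_{approach}_{unit}.csv", index=False
                    )
            results.setdefault("evaluation", {})[unit] = evals

    # pregnancy rate from the mixture labels on unknown-status females
    first_unit = config.unit_metrics[0]
    table = results["classifications"][first_unit]
    blind = table[(table["status"] == "unknown") & table["colour_class"].notna()]
    if "mixture" in config.approaches and len(blind):
        est = rate_from_labels(
            blind["label_mixture"],
            blind["colour_class"],
            n_virtual=n_virtual,
            schedule=config.maturity_schedule,
        )
        results["pregnancy_rate"] = est
        pd.DataFrame(
            [
                {
                    "n_pregnant": est.n_pregnant,
                    "min_mature": est.min_mature,
                    "additional_mature": est.additional_mature,
                    "adjusted_denominator": est.adjusted_denominator,
                    "raw_rate": est.raw_rate,
                    "adjusted_rate": est.adjusted_rate,
                }
            ]
        ).to_csv(outdir / "pregnancy_rate.csv", index=False)

    manifest = {
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "seed": config.seed,
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
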