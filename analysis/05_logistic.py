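"""Bayesian logistic regression of pregnancy on log BP: trained on the
known-status carcasses, predicting the unknown-status individuals
(including the recently parturient females) as missing responses.

Reads results/data/analysis_table.csv; writes coefficient summaries and
per-sample probabilities to results/classification/.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from belugapreg.logistic import classify_by_probability, equal_odds_point, fit_logistic
from belugapreg.mixture import MCMCSettings
from belugapreg.samples import read_samples


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/classification"))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--full-mcmc", action="store_true")
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    settings = (
        MCMCSettings(seed=args.seed) if args.full_mcmc else MCMCSettings.scaled(seed=args.seed)
    )
    df = read_samples(args.datadir / "analysis_table.csv")
    df = df[~df["is_virtual"] & df["bp_tissue_ng_g"].notna()]
    known = df[df["status"] != "unknown"]
    unknown = df[df["status"] == "unknown"]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit, pred = fit_logistic(known, unknown, settings=settings, unit="tissue")

    pred = pred.copy()
    pred["label_logistic"] = classify_by_probability(pred["p_pregnant"].to_numpy())
    pred.to_csv(args.outdir / "logistic_predictions.csv", index=False)

    orr = fit.odds_ratio()
    eo = equal_odds_point(fit)
    summary = pd.DataFrame(
        [
            {"quantity": "beta0", "mean": fit.flat("beta0").mean(),
             "ci_low": np.percentile(fit.flat("beta0"), 2.5),
             "ci_high": np.percentile(fit.flat("beta0"), 97.5)},
            {"quantity": "beta1", "mean": fit.flat("beta1").mean(),
             "ci_low": np.percentile(fit.flat("beta1"), 2.5),
             "ci_high": np.percentile(fit.flat("beta1"), 97.5)},
            {"quantity": "odds_ratio_per_log_unit", **orr},
            {"quantity": "equal_odds_ng_g", **eo},
        ]
    )
    summary.to_csv(args.outdir / "logistic_summary.csv", index=False)

    print(
        f"odds of pregnancy x{orr['mean']:.1f} [{orr['ci_low']:.1f}, "
        f"{orr['ci_high']:.1f}] per unit log BP"
    )
    print(f"equal odds at {eo['mean']:.1f} [{eo['ci_low']:.1f}, {eo['ci_high']:.1f}] ng/g")
    n_preg = int((pred["label_logistic"] == "pregnant").sum())
    print(f"predicted pregnant: {n_preg}/{len(pred)} unknown-status individuals")


if __name__ == "__main__":
    main()
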