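"""Fixed-threshold classification on both unit metrics (100 ng/g tissue,
150 ng/g lipid) and the unit-switch accounting.

Reads results/data/analysis_table.csv; writes
results/classification/threshold_{tissue,lipid}.csv and prints the
switch fraction with its lipid-content breakdown.
"""

import argparse
from pathlib import Path

from belugapreg.evaluation import unit_switch_fraction
from belugapreg.samples import read_samples
from belugapreg.threshold import DEFAULT_THRESHOLDS, ThresholdRule, classify_fixed_threshold


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/classification"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    df = read_samples(args.datadir / "analysis_table.csv")
    df = df[~df["is_virtual"]]

    labels = {}
    for unit, col in (("tissue", "bp_tissue_ng_g"), ("lipid", "bp_lipid_ng_g")):
        rule = ThresholdRule(DEFAULT_THRESHOLDS[unit], unit_metric=unit)
        sub = df[df[col].notna()].copy()
        sub[f"label_threshold_{unit}"] = classify_fixed_threshold(
            sub[col].to_numpy(), rule, values_unit=unit
        )
        out = sub[["sample_id", "program", "status", col, f"label_threshold_{unit}"]]
        out.to_csv(args.outdir / f"threshold_{unit}.csv", index=False)
        n_preg = int((sub[f"label_threshold_{unit}"] == "pregnant").sum())
        print(f"{unit}: {n_preg}/{len(sub)} classified pregnant at {rule.threshold} ng/g")
        labels[unit] = sub.set_index("sample_id")[f"label_threshold_{unit}"]

    both = labels["tissue"].index.intersection(labels["lipid"].index)
    lipids = df.set_index("sample_id").loc[both, "lipid_fraction"]
    rep = unit_switch_fraction(
        labels["tissue"].loc[both], labels["lipid"].loc[both], lipids
    )
    print(f"unit-switch fraction: {rep.fraction:.1%} of {rep.n} samples")
    switched = rep.table[rep.table["switched"]]
    if len(switched):
        print(
            f"switchers' lipid content: max {switched['lipid_fraction'].max():.1%} "
            f"(n={len(switched)})"
        )


if __name__ == "__main__":
    main()
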