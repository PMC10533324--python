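"""Score each approach against the known reproductive statuses.

Joins the classification tables from 03-05 on the known-status carcass
rows, adjudicates expected labels (recently parturient females count as
expected-pregnant), and tallies misclassifications per approach.

Writes results/evaluation/errors_by_approach.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from belugapreg.evaluation import expected_label, misclassification_count


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--clsdir", type=Path, default=Path("results/classification"))
    parser.add_argument("--outdir", type=Path, default=Path("results/evaluation"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    # the logistic fit trains on most known-status rows and predicts only
    # the withheld recently parturient females; rebuild a full label set
    # by giving trained rows their coded response back
    knowns = pd.read_csv(args.clsdir / "threshold_tissue.csv")
    knowns = knowns[knowns["status"] != "unknown"][["sample_id", "status"]]
    preds = pd.read_csv(args.clsdir / "logistic_predictions.csv")
    logistic = knowns.merge(
        preds[["sample_id", "label_logistic"]], on="sample_id", how="left"
    )
    trained = logistic["label_logistic"].isna()
    logistic.loc[trained, "label_logistic"] = [
        "pregnant" if s == "pregnant" else "non-pregnant"
        for s in logistic.loc[trained, "status"]
    ]
    logistic_path = args.outdir / "logistic_full_labels.csv"
    logistic.to_csv(logistic_path, index=False)

    sources = {
        "threshold_tissue": (args.clsdir / "threshold_tissue.csv", "label_threshold_tissue"),
        "threshold_lipid": (args.clsdir / "threshold_lipid.csv", "label_threshold_lipid"),
        "mixture": (args.clsdir / "mixture_SLE_carcass.csv", "label_mixture"),
        "logistic": (logistic_path, "label_logistic"),
    }

    rows = []
    for approach, (path, label_col) in sources.items():
        table = pd.read_csv(path)
        known = table[table["status"].isin(
            ["pregnant", "recent_parturition", "lactating", "resting",
             "immature_female", "immature_male", "mature_male"]
        )]
        if not len(known):
            continue
        expected = known["status"].map(expected_label).to_numpy()
        rep = misclassification_count(
            known[label_col].to_numpy(), expected, statuses=known["status"].to_numpy()
        )
        rows.append({"approach": approach, "errors": rep.count, "n": rep.n})
        print(f"{approach}: {rep.count} misclassifications over {rep.n} known-status samples")
        detail = rep.by_status[rep.by_status["errors"] > 0]
        if len(detail):
            print(detail.to_string(index=False))

    pd.DataFrame(rows).to_csv(args.outdir / "errors_by_approach.csv", index=False)


if __name__ == "__main__":
    main()
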