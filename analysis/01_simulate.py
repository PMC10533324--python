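"""Generate the synthetic sample tables the downstream analyses run on.

Emulates the three sampling programs: known-status necropsied carcasses
(seven reproductive-status groups at their published raw-scale moments),
freshly harvested carcasses of unknown status (two BP clusters, high
lipid), blind biopsies of free-ranging females (three BP clusters, low
lipid), plus the virtual biopsies (lactating females recorded without a
BP value).

Writes results/data/*.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from belugapreg.samples import write_samples
from belugapreg.synthetic import (
    KNOWN_STATUS_GROUPS,
    biopsy_population,
    nunavik_population,
    simulate_known_samples,
    simulate_unknown_population,
)


def virtual_biopsies(n: int = 9) -> pd.DataFrame:
    colours = (["white", "off-white", "grey"] * n)[:n]
    return pd.DataFrame(
        {
            "sample_id": [f"virtual_{i:02d}" for i in range(n)],
            "program": "virtual_biopsy",
            "sex": "female",
            "colour_class": colours,
            "status": "lactating",
            "bp_tissue_ng_g": np.nan,
            "bp_lipid_ng_g": np.nan,
            "lipid_fraction": np.nan,
            "lipid_imputed": False,
            "is_virtual": True,
            "latent_truth": pd.NA,
        }
    )


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    known = simulate_known_samples(KNOWN_STATUS_GROUPS, seed=args.seed)
    nunavik = simulate_unknown_population(nunavik_population(), 135, seed=args.seed + 1)
    biopsies = simulate_unknown_population(biopsy_population(), 65, seed=args.seed + 2)
    virtual = virtual_biopsies(9)

    for name, table in (
        ("known_carcasses", known),
        ("nunavik_carcasses", nunavik),
        ("blind_biopsies", biopsies),
        ("virtual_biopsies", virtual),
    ):
        write_samples(table, args.outdir / f"{name}.csv")
        print(f"{name}: {len(table)} rows -> {args.outdir / f'{name}.csv'}")

    summary = known.groupby("status")["bp_tissue_ng_g"].agg(["count", "mean", "std"])
    print("\nknown-status BP (ng/g tissue):")
    print(summary.round(1).to_string())


if __name__ == "__main__":
    main()
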