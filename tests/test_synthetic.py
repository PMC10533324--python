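"""The generator must hit the group moments it is asked for, be exactly
reproducible under a fixed seed, and keep the latent truth out of the
columns classifiers consume."""

import numpy as np
import pandas as pd
import pytest

from belugapreg.samples import CLASSIFIER_COLUMNS, SCHEMA_COLUMNS
from belugapreg.synthetic import (
    GroupSpec,
    KNOWN_STATUS_GROUPS,
    PopulationSpec,
    biopsy_population,
    lognormal_params,
    nunavik_population,
    simulate_known_samples,
    simulate_lipid_fractions,
    simulate_unknown_population,
)


class TestKnownSamples:
    def test_empty_specs_give_empty_table(self):
        df = simulate_known_samples([], seed=0)
        assert len(df) == 0
        assert list(df.columns) == SCHEMA_COLUMNS

    def test_zero_sd_is_degenerate_at_the_mean(self):
        df = simulate_known_samples([GroupSpec("pregnant", 1000, 365.0, 0.0)], seed=0)
        assert (df["bp_tissue_ng_g"] == 365.0).all()

    def test_moment_matching_at_large_n(self):
        """Raw-scale sample moments converge to the requested mean/SD.

        Oracle: the lognormal moment-matching identities, checked by
        direct simulation at n = 10^4.
        """
        n = 10_000
        df = simulate_known_samples([GroupSpec("pregnant", n, 365.0, 244.0)], seed=3)
        x = df["bp_tissue_ng_g"].to_numpy()
        se = x.std(ddof=1) / np.sqrt(n)
        assert abs(x.mean() - 365.0) < 2 * se
        assert abs(x.std(ddof=1) - 244.0) / 244.0 < 0.05

    def test_default_groups_reproduce_published_moments(self):
        means = {g.status: g.mean_raw for g in KNOWN_STATUS_GROUPS}
        assert means == {
            "immature_male": 1.1,
            "mature_male": 0.8,
            "immature_female": 0.6,
            "resting": 3.1,
            "pregnant": 365.0,
            "recent_parturition": 273.0,
            "lactating": 38.4,
        }
        assert sum(g.n for g in KNOWN_STATUS_GROUPS) == 62

    def test_non_positive_mean_names_the_group(self):
        with pytest.raises(ValueError, match="lactating"):
            GroupSpec("lactating", 5, 0.0, 1.0)

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_known_samples(KNOWN_STATUS_GROUPS, seed=9)
        b = simulate_known_samples(KNOWN_STATUS_GROUPS, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestUnknownPopulation:
    def test_degenerate_weight_gives_single_label(self):
        spec = PopulationSpec(
            weights=(1.0, 0.0),
            components=(GroupSpec("resting", 0, 3.0, 1.0), GroupSpec("pregnant", 0, 365.0, 1.0)),
        )
        df = simulate_unknown_population(spec, 50, seed=0)
        assert (df["latent_truth"] == "resting").all()

    def test_label_proportions_match_weights(self):
        """Binomial-SE oracle on the empirical component proportions."""
        n = 10_000
        spec = PopulationSpec(
            weights=(0.5, 0.5),
            components=(GroupSpec("resting", 0, 3.0, 1.0), GroupSpec("pregnant", 0, 365.0, 100.0)),
        )
        df = simulate_unknown_population(spec, n, seed=4)
        frac = (df["latent_truth"] == "pregnant").mean()
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 2 * se

    def test_biopsy_lipid_mean_matches_program(self):
        df = simulate_unknown_population(biopsy_population(), 5000, seed=5)
        assert abs(df["lipid_fraction"].mean() - 0.243) < 0.01

    def test_negative_n_errors(self):
        with pytest.raises(ValueError):
            simulate_unknown_population(biopsy_population(), -1, seed=0)

    def test_latent_truth_not_in_classifier_columns(self):
        assert "latent_truth" not in CLASSIFIER_COLUMNS
        df = simulate_unknown_population(biopsy_population(), 10, seed=0)
        assert set(CLASSIFIER_COLUMNS) | {"latent_truth"} == set(df.columns)

    def test_per_lipid_unit_consistency(self):
        df = simulate_unknown_population(nunavik_population(), 200, seed=6)
        np.testing.assert_allclose(
            df["bp_lipid_ng_g"], df["bp_tissue_ng_g"] / df["lipid_fraction"]
        )


class TestLipidFractions:
    def test_zero_sd_returns_constant(self):
        assert (simulate_lipid_fractions(0.3, 0.0, 100, seed=0) == 0.3).all()

    def test_beta_moment_matching(self):
        n = 10_000
        x = simulate_lipid_fractions(0.664, 0.1, n, seed=1)
        assert abs(x.mean() - 0.664) < 2 * x.std(ddof=1) / np.sqrt(n)
        assert ((x > 0) & (x <= 1)).all()

    def test_carcass_vs_biopsy_lipid_contrast(self):
        """Carcass lipid runs about 2.6-2.7-fold above biopsy lipid."""
        carcass = simulate_lipid_fractions(0.664, 0.1, 5000, seed=2).mean()
        biopsy = simulate_lipid_fractions(0.243, 0.15, 5000, seed=3).mean()
        assert 2.4 < carcass / biopsy < 3.0

    def test_infeasible_moment_pair_errors(self):
        with pytest.raises(ValueError, match="Beta"):
            simulate_lipid_fractions(0.5, 0.6, 10, seed=0)
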