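"""Bayesian logistic regression: coding, recovery, derived quantities."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from belugapreg._rng import spawn_rng
from belugapreg.logistic import (
    LogisticFit,
    classify_by_probability,
    code_response,
    equal_odds_point,
    fit_logistic,
    fit_logistic_arrays,
)
from belugapreg.mixture import MCMCSettings
from belugapreg.synthetic import KNOWN_STATUS_GROUPS, simulate_known_samples


def constructed_fit(b0, b1):
    """A LogisticFit with point-mass posterior draws."""
    return LogisticFit(
        beta0=np.full((1, 4), float(b0)), beta1=np.full((1, 4), float(b1))
    )


@pytest.fixture(scope="module")
def settings():
    return MCMCSettings(n_iterations=3000, n_chains=2, thin=2, burn_in=1000, seed=23)


class TestResponseCoding:
    def test_coding_rules(self):
        assert code_response("pregnant") == 1
        for s in ("mature_male", "immature_male", "immature_female", "resting", "lactating"):
            assert code_response(s) == 0
        # recently parturient females are predicted, not trained on
        assert code_response("recent_parturition") is None
        assert code_response("unknown") is None

    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError):
            code_response("calf")


class TestFit:
    def test_null_effect_interval_contains_one(self, settings):
        """Labels independent of BP: odds-ratio CI must cover 1."""
        rng = spawn_rng(11, "null")
        x = rng.uniform(0, 7, 200)
        y = (rng.uniform(size=200) < 0.5).astype(int)
        fit = fit_logistic_arrays(x, y, settings=settings)
        orr = fit.odds_ratio()
        assert orr["ci_low"] < 1 < orr["ci_high"]

    def test_parameter_recovery(self, settings):
        """Generating (beta0, beta1) = (-8, 2), n = 500: both 95% credible
        intervals cover the truth."""
        rng = spawn_rng(12, "recover")
        x = rng.uniform(0, 7, 500)
        y = (rng.uniform(size=500) < expit(-8 + 2 * x)).astype(int)
        fit = fit_logistic_arrays(x, y, settings=settings)
        for draws, truth in ((fit.flat("beta0"), -8.0), (fit.flat("beta1"), 2.0)):
            lo, hi = np.percentile(draws, [2.5, 97.5])
            assert lo < truth < hi
        assert fit.converged

    def test_single_class_training_rejected(self, settings):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic_arrays([1.0, 2.0, 3.0], [1, 1, 1], settings=settings)

    def test_complete_separation_warns(self, settings):
        x = np.concatenate([np.linspace(0, 1, 20), np.linspace(5, 6, 20)])
        y = np.concatenate([np.zeros(20, int), np.ones(20, int)])
        with pytest.warns(UserWarning, match="separated"):
            fit_logistic_arrays(x, y, settings=settings)

    def test_monotone_predictions_with_positive_slope(self, settings):
        rng = spawn_rng(13, "mono")
        x = rng.uniform(0, 7, 300)
        y = (rng.uniform(size=300) < expit(-4 + 1.5 * x)).astype(int)
        fit = fit_logistic_arrays(x, y, settings=settings)
        assert fit.flat("beta1").min() > 0
        grid = np.linspace(-1, 8, 30)
        p = fit.predict_probability(grid)
        assert (np.diff(p) >= 0).all()

    def test_dataframe_interface_withholds_recent_parturition(self, settings):
        """Recently parturient females leave training and get predictions."""
        known = simulate_known_samples(KNOWN_STATUS_GROUPS, seed=21)
        fit, pred = fit_logistic(known, settings=settings)
        assert set(pred["status"]) == {"recent_parturition"}
        assert len(pred) == 10
        assert ((pred["p_pregnant"] >= 0) & (pred["p_pregnant"] <= 1)).all()
        # high-BP recent mothers keep a pregnancy-like signal
        high = pred[pred["bp_tissue_ng_g"] > 150]
        assert (high["p_pregnant"] > 0.5).all()


class TestClassifyByProbability:
    def test_half_is_pregnant_boundary_inclusive(self):
        labels = classify_by_probability([0.49, 0.50, 1.0])
        assert labels.tolist() == ["non-pregnant", "pregnant", "pregnant"]

    def test_cutoff_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            classify_by_probability([0.5], cutoff=1.0)

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            classify_by_probability([1.2])


class TestEqualOdds:
    def test_closed_form_inversion(self):
        assert equal_odds_point(constructed_fit(-4.6052, 1.0))["mean"] == pytest.approx(
            100.0, rel=1e-3
        )
        assert equal_odds_point(constructed_fit(0.0, 2.0))["mean"] == 1.0

    def test_slope_straddling_zero_errors(self):
        fit = LogisticFit(
            beta0=np.zeros((1, 4)), beta1=np.array([[-0.5, 0.5, 1.0, 2.0]])
        )
        with pytest.raises(ValueError, match="straddle"):
            equal_odds_point(fit)

    def test_probability_is_half_at_equal_odds_per_draw(self, settings):
        """Algebraic identity: expit(b0 + b1 * log(exp(-b0/b1))) = 0.5
        exactly, draw by draw."""
        rng = spawn_rng(14, "identity")
        x = rng.uniform(0, 7, 300)
        y = (rng.uniform(size=300) < expit(-5 + 1.5 * x)).astype(int)
        fit = fit_logistic_arrays(x, y, settings=settings)
        b0, b1 = fit.flat("beta0"), fit.flat("beta1")
        p = expit(b0 + b1 * (-b0 / b1))
        np.testing.assert_allclose(p, 0.5, atol=1e-12)
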