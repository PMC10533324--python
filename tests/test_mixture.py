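"""Gaussian-mixture MCMC: geometry, diagnostics, WAIC, membership.

arviz serves as the independent oracle for WAIC (same retained draws fed
to both routes); the Gelman-Rubin statistic is checked against a
closed-form hand computation on constructed chains.
"""

import numpy as np
import pytest

from belugapreg.mixture import (
    MCMCSettings,
    MixtureFit,
    compute_waic,
    fit_mixture,
    gelman_rubin,
    label_clusters,
    posterior_membership,
    select_mixture,
)
from belugapreg.synthetic import lognormal_params
from belugapreg._rng import spawn_rng


def point_mass_fit(mu, sigma, w, n_draws=4):
    """A MixtureFit whose every draw equals the given parameters."""
    K = len(mu)
    shape = (1, n_draws, K)
    return MixtureFit(
        K=K,
        mu=np.broadcast_to(np.asarray(mu, float), shape).copy(),
        sigma=np.broadcast_to(np.asarray(sigma, float), shape).copy(),
        w=np.broadcast_to(np.asarray(w, float), shape).copy(),
        log_lik=np.zeros((1, n_draws, 1)),
        n_obs=1,
    )


class TestSettings:
    def test_default_geometry_keeps_1000_draws_per_chain(self):
        assert MCMCSettings().draws_per_chain == 1000
        assert MCMCSettings.scaled().draws_per_chain == 1000

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_iterations=100, burn_in=100),
            dict(n_iterations=103, burn_in=5, thin=10),
            dict(n_chains=0),
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MCMCSettings(**kwargs)


class TestGelmanRubin:
    def test_duplicated_chains_give_one(self):
        rng = spawn_rng(0, "gr")
        chain = rng.normal(size=200)
        assert gelman_rubin(np.stack([chain, chain])) == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_on_shifted_chains(self):
        """Two chains with means 0 and 10, within-chain SD 1, length 100.

        Hand computation: W = 1, B = 100 * 50, so
        R-hat = sqrt((99/100 * 1 + 50) / 1) = sqrt(50.99).
        """
        rng = spawn_rng(1, "gr")
        z = rng.normal(size=100)
        z = (z - z.mean()) / z.std(ddof=1)  # exact mean 0, sd 1
        rhat = gelman_rubin(np.stack([z, z + 10]))
        assert rhat == pytest.approx(np.sqrt(50.99), rel=1e-9)
        assert rhat > 5

    def test_single_chain_errors(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))

    def test_converged_fit_has_small_rhat(self, carcass_fit2):
        assert all(v < 1.1 for v in carcass_fit2.rhat.values())
        assert carcass_fit2.converged


class TestFitMixture:
    def test_k1_collapses_to_normal_model(self, fast_settings):
        rng = spawn_rng(2, "k1")
        y = rng.normal(3.0, 1.0, size=80)
        fit = fit_mixture(y, 1, fast_settings)
        mu = fit.flat("mu")[:, 0]
        assert abs(mu.mean() - y.mean()) < 2 * mu.std()

    def test_two_component_parameter_recovery(self, fast_settings):
        """Single-replicate recovery of the generating log-means.

        Data from the resting/pregnant raw moments via the lognormal
        moment-matching oracle; each posterior mean must fall within 3
        posterior SDs of its generating value.
        """
        rng = spawn_rng(3, "recovery")
        mu_lo, sd_lo = lognormal_params(3.1, 4.5)
        mu_hi, sd_hi = lognormal_params(365.0, 244.0)
        y = np.concatenate(
            [rng.normal(mu_lo, sd_lo, 100), rng.normal(mu_hi, sd_hi, 100)]
        )
        fit = fit_mixture(y, 2, fast_settings)
        for k, truth in enumerate([mu_lo, mu_hi]):
            draws = fit.flat("mu")[:, k]
            assert abs(draws.mean() - truth) < 3 * draws.std()

    def test_carcass_like_data_prefers_two_clusters(self, carcass_logbp, fast_settings):
        best, fits = select_mixture(carcass_logbp, fast_settings, ks=(1, 2))
        assert best.K == 2
        assert fits[2].waic < fits[1].waic

    def test_ordered_means_in_every_retained_draw(self, carcass_fit2):
        mu = carcass_fit2.flat("mu")
        assert (np.diff(mu, axis=1) > 0).all()

    def test_fixed_seed_is_bit_reproducible(self, carcass_logbp):
        s = MCMCSettings(n_iterations=400, n_chains=2, thin=2, burn_in=200, seed=5)
        a = fit_mixture(carcass_logbp, 2, s)
        b = fit_mixture(carcass_logbp, 2, s)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_too_few_observations_rejected(self, fast_settings):
        with pytest.raises(ValueError):
            fit_mixture(np.array([1.0, 2.0]), 2, fast_settings)


class TestWaic:
    def test_recomputation_is_deterministic(self, carcass_fit2, carcass_logbp):
        a = compute_waic(carcass_fit2, carcass_logbp)
        b = compute_waic(carcass_fit2, carcass_logbp)
        assert a == b == carcass_fit2.waic

    def test_data_mismatch_errors(self, carcass_fit2):
        with pytest.raises(ValueError, match="does not match"):
            compute_waic(carcass_fit2, np.zeros(5))

    def test_agrees_with_arviz_on_the_same_draws(self, carcass_fit2, carcass_logbp):
        """Independent WAIC route: arviz on the identical retained draws."""
        az = pytest.importorskip("arviz")
        idata = az.from_dict(
            log_likelihood={"y": carcass_fit2.log_lik}
        )
        ref = az.waic(idata, scale="deviance")
        # routes differ only in variance estimator details
        assert carcass_fit2.waic == pytest.approx(float(ref.elpd_waic), abs=0.05)


class TestMembership:
    def test_rows_sum_to_one(self, carcass_fit2):
        values = np.array([0.5, 3.0, 17.0, 55.0, 100.0, 365.0, 800.0])
        prob = posterior_membership(carcass_fit2, values)
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-9)

    def test_separation_limit(self):
        """A value at one component's mean, 10+ SDs from the other,
        belongs to that component with probability ~ 1."""
        fit = point_mass_fit([0.0, 20.0], [1.0, 1.0], [0.5, 0.5])
        prob = posterior_membership(fit, [np.exp(0.0), np.exp(20.0)])
        assert prob[0, 0] > 1 - 1e-9
        assert prob[1, 1] > 1 - 1e-9

    def test_midpoint_is_equivocal(self):
        fit = point_mass_fit([0.0, 4.0], [1.0, 1.0], [0.5, 0.5])
        prob = posterior_membership(fit, [np.exp(2.0)])
        assert prob[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_intermediate_probability_ordering(self, carcass_fit2):
        """Pregnant-cluster probability rises with concentration."""
        prob = posterior_membership(carcass_fit2, [3.0, 17.0, 55.0, 365.0])
        p_high = prob[:, carcass_fit2.pregnant_cluster]
        assert (np.diff(p_high) > 0).all()
        assert p_high[0] < 0.5 < p_high[-1]

    def test_non_positive_value_rejected(self, carcass_fit2):
        with pytest.raises(ValueError):
            posterior_membership(carcass_fit2, [0.0])


class TestLabels:
    def test_two_component_labels(self):
        fit = point_mass_fit([1.0, 5.9], [1.0, 1.0], [0.5, 0.5])
        assert label_clusters(fit) == ["non-pregnant", "pregnant"]
        assert fit.pregnant_cluster == 1

    def test_three_component_labels(self):
        fit = point_mass_fit([0.0, 3.5, 5.5], [1.0] * 3, [1 / 3] * 3)
        assert label_clusters(fit) == ["non-pregnant", "intermediate", "pregnant"]

    def test_single_component_warns_undifferentiated(self):
        fit = point_mass_fit([2.0], [1.0], [1.0])
        with pytest.warns(UserWarning, match="undifferentiated"):
            assert label_clusters(fit) == ["undifferentiated"]
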