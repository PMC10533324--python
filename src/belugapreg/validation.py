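"""Simulation-based validation studies for the Bayesian estimators.

Parameter-recovery checks: simulate data with known generating values at
the study's group moments, fit the model, and score credible-interval
coverage and WAIC model preference over seeded replicates. These studies
are what the test suite and the reproduction script run; they stand in
for ground truth that free-ranging data cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ._rng import spawn_rng
from .logistic import fit_logistic_arrays
from .mixture import MCMCSettings, fit_mixture
from .synthetic import lognormal_params

__all__ = [
    "MixtureRecoveryResult",
    "mixture_recovery_study",
    "logistic_recovery_check",
]


@dataclass
class MixtureRecoveryResult:
    """Per-replicate outcomes of the two-component recovery study."""

    n_replicates: int
    covered_low: int  # replicates whose 95% CI covers the low log-mean
    covered_high: int
    waic_prefers_two: int  # replicates with WAIC(K=2) < WAIC(K=1)
    generating_log_means: tuple


def mixture_recovery_study(
    n_replicates: int = 20,
    n_per_component: int = 100,
    low_moments: tuple = (3.1, 4.5),
    high_moments: tuple = (365.0, 244.0),
    seed: int = 0,
) -> MixtureRecoveryResult:
    """Two-component recovery at the resting vs pregnant group moments.

    Each replicate simulates ``n_per_component`` log-normal draws per
    component (moment matched to the raw-scale mean/SD), fits K = 1 and
    K = 2 mixtures at the scaled MCMC geometry, and records whether each
    95% credible interval covers its generating log-mean and whether
    WAIC prefers two components.
    """
    mu_lo, sd_lo = lognormal_params(*low_moments)
    mu_hi, sd_hi = lognormal_params(*high_moments)
    covered_lo = covered_hi = prefers_two = 0
    for rep in range(n_replicates):
        rng = spawn_rng(seed, "mixture_recovery", rep)
        y = np.concatenate(
            [
                rng.normal(mu_lo, sd_lo, n_per_component),
                rng.normal(mu_hi, sd_hi, n_per_component),
            ]
        )
        settings = MCMCSettings.scaled(seed=seed * 1000 + rep)
        fit2 = fit_mixture(y, 2, settings)
        fit1 = fit_mixture(y, 1, settings)
        lo_ci = np.percentile(fit2.flat("mu")[:, 0], [2.5, 97.5])
        hi_ci = np.percentile(fit2.flat("mu")[:, 1], [2.5, 97.5])
        covered_lo += int(lo_ci[0] <= mu_lo <= lo_ci[1])
        covered_hi += int(hi_ci[0] <= mu_hi <= hi_ci[1])
        prefers_two += int(fit2.waic < fit1.waic)
    return MixtureRecoveryResult(
        n_replicates=n_replicates,
        covered_low=covered_lo,
        covered_high=covered_hi,
        waic_prefers_two=prefers_two,
        generating_log_means=(mu_lo, mu_hi),
    )


def logistic_recovery_check(
    beta0: float = -8.0, beta1: float = 2.0, n: int = 500, seed: int = 0
):
    """Fit the logistic model to data generated at known coefficients.

    Returns the fit plus per-coefficient 95% credible intervals and
    coverage flags for the generating values.
    """
    rng = spawn_rng(seed, "logistic_recovery")
    x = rng.uniform(0.0, 7.0, n)  # log BP over the plausible range
    y = (rng.uniform(size=n) < expit(beta0 + beta1 * x)).astype(int)
    fit = fit_logistic_arrays(x, y, settings=MCMCSettings.scaled(seed=seed))
    ci0 = np.percentile(fit.flat("beta0"), [2.5, 97.5])
    ci1 = np.percentile(fit.flat("beta1"), [2.5, 97.5])
    return {
        "fit": fit,
        "ci_beta0": tuple(ci0),
        "ci_beta1": tuple(ci1),
        "covers_beta0": bool(ci0[0] <= beta0 <= ci0[1]),
        "covers_beta1": bool(ci1[0] <= beta1 <= ci1[1]),
    }
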