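"""Bayesian logistic regression of pregnancy on natural-log BP.

The model: for individuals of known reproductive status,

    pregnant_i ~ Bernoulli(p_i),   logit(p_i) = beta0 + beta1 * log(BP_i),

with weakly informative Normal(0, 10) priors on both coefficients.
Response coding: confirmed pregnant females are 1; males, lactating,
immature and resting females are 0. Females sampled shortly after giving
birth are withheld from training — their blubber progesterone may sit
anywhere between pregnant and non-pregnant levels — and are predicted as
missing responses instead, which a Bayesian fit handles directly: each
posterior draw implies a probability for every unknown individual, and
the posterior mean of those probabilities is reported.

Derived quantities per draw: the odds ratio exp(beta1) (multiplicative
change in the odds of pregnancy per unit of log BP) and the equal-odds
concentration exp(-beta0/beta1), the BP value at which the model returns
probability 0.5.

Sampling is random-walk Metropolis started at the posterior mode with a
proposal covariance from the Laplace approximation, run as independent
chains with the same geometry (iterations/burn-in/thinning) as the
mixture fits, and monitored with Gelman-Rubin diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from ._rng import spawn_rng
from .mixture import MCMCSettings, RHAT_THRESHOLD, ConvergenceWarning, gelman_rubin

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "fit_logistic_arrays",
    "classify_by_probability",
    "equal_odds_point",
    "code_response",
]

_PRIOR_SD = 10.0

#: Response coding for training; None = withheld and predicted instead.
_TRAIN_CODE = {
    "pregnant": 1,
    "resting": 0,
    "lactating": 0,
    "immature_female": 0,
    "immature_male": 0,
    "mature_male": 0,
    "recent_parturition": None,
    "unknown": None,
}


def code_response(status: str) -> int | None:
    """0/1 training code for a reproductive status, or None if predicted."""
    if status not in _TRAIN_CODE:
        raise ValueError(f"unknown reproductive status: {status!r}")
    return _TRAIN_CODE[status]


@dataclass
class LogisticFit:
    """Posterior draws and derived summaries for the logistic model."""

    beta0: np.ndarray  # (n_chains, draws_per_chain)
    beta1: np.ndarray
    rhat: dict = field(default_factory=dict)
    predicted_probabilities: np.ndarray | None = None
    settings: MCMCSettings | None = None

    @property
    def converged(self) -> bool:
        return all(v < RHAT_THRESHOLD for v in self.rhat.values())

    def flat(self, name: str) -> np.ndarray:
        return getattr(self, name).ravel()

    def odds_ratio(self) -> dict:
        """exp(beta1): posterior mean and central 95% credible interval."""
        orr = np.exp(self.flat("beta1"))
        lo, hi = np.percentile(orr, [2.5, 97.5])
        return {"mean": float(orr.mean()), "ci_low": float(lo), "ci_high": float(hi)}

    def predict_probability(self, log_bp) -> np.ndarray:
        """Posterior-mean pregnancy probability at the given log BP values."""
        x = np.atleast_1d(np.asarray(log_bp, dtype=float))
        b0, b1 = self.flat("beta0"), self.flat("beta1")
        return expit(b0[:, None] + b1[:, None] * x[None, :]).mean(axis=0)


def _log_posterior(theta, x, y):
    eta = theta[0] + theta[1] * x
    loglik = np.sum(np.where(y == 1, log_expit(eta), log_expit(-eta)))
    return loglik - np.sum(theta**2) / (2 * _PRIOR_SD**2)


def fit_logistic_arrays(
    x_train, y_train, x_predict=None, settings: MCMCSettings | None = None
) -> LogisticFit:
    """Fit the logistic model on (log BP, 0/1) training arrays.

    ``x_predict`` holds log BP of missing-response individuals whose
    pregnancy probability is returned as ``predicted_probabilities``.
    """
    if settings is None:
        settings = MCMCSettings()
    x = np.asarray(x_train, dtype=float)
    y = np.asarray(y_train, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x_train and y_train must be aligned 1-D arrays")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if x[y == 0].max() < x[y == 1].min() or x[y == 1].max() < x[y == 0].min():
        warnings.warn(
            "classes are completely separated in log BP; the priors regularize "
            "the fit but the slope is prior-sensitive",
            stacklevel=2,
        )

    # posterior mode + Laplace covariance for the proposal
    neg = lambda t: -_log_posterior(t, x, y)
    opt = minimize(neg, np.zeros(2), method="BFGS")
    mode = opt.x
    cov = opt.hess_inv if np.all(np.isfinite(opt.hess_inv)) else np.eye(2)
    cov = (cov + cov.T) / 2 + 1e-9 * np.eye(2)
    prop_chol = np.linalg.cholesky(2.4**2 / 2 * cov)

    draws = settings.draws_per_chain
    b0 = np.empty((settings.n_chains, draws))
    b1 = np.empty((settings.n_chains, draws))
    for c in range(settings.n_chains):
        rng = spawn_rng(settings.seed, "logistic", c)
        theta = mode + prop_chol @ rng.standard_normal(2)  # overdispersed start
        lp = _log_posterior(theta, x, y)
        kept = 0
        for it in range(settings.n_iterations):
            prop = theta + prop_chol @ rng.standard_normal(2)
            lp_prop = _log_posterior(prop, x, y)
            if np.log(rng.uniform()) < lp_prop - lp:
                theta, lp = prop, lp_prop
            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                b0[c, kept], b1[c, kept] = theta
                kept += 1

    fit = LogisticFit(beta0=b0, beta1=b1, settings=settings)
    if settings.n_chains >= 2:
        fit.rhat = {"beta0": gelman_rubin(b0), "beta1": gelman_rubin(b1)}
        if not fit.converged:
            warnings.warn(
                f"logistic fit may not have converged; R-hat: {fit.rhat}",
                ConvergenceWarning,
                stacklevel=2,
            )
    if x_predict is not None and len(x_predict):
        fit.predicted_probabilities = fit.predict_probability(x_predict)
    return fit


def fit_logistic(
    known: pd.DataFrame,
    unknown: pd.DataFrame | None = None,
    settings: MCMCSettings | None = None,
    unit: str = "tissue",
) -> tuple[LogisticFit, pd.DataFrame]:
    """Fit on known-status samples; predict unknowns as missing responses.

    ``known`` rows with status ``recent_parturition`` are moved to the
    prediction set (their status is what the model is asked to estimate).
    Returns the fit and a table of per-sample posterior mean probabilities
    for everything predicted.
    """
    col = {"tissue": "bp_tissue_ng_g", "lipid": "bp_lipid_ng_g"}[unit]
    codes = known["status"].map(code_response)
    train = known[codes.notna()]
    withheld = known[codes.isna()]
    pred_frames = [withheld] + ([unknown] if unknown is not None else [])
    predict = pd.concat(pred_frames, ignore_index=False) if pred_frames else withheld
    predict = predict[predict[col].notna()]

    x_train = np.log(train[col].to_numpy(dtype=float))
    y_train = codes[codes.notna()].to_numpy(dtype=int)
    x_pred = np.log(predict[col].to_numpy(dtype=float))
    fit = fit_logistic_arrays(x_train, y_train, x_pred, settings)
    out = predict[["sample_id", "status", col]].copy()
    out["p_pregnant"] = fit.predicted_probabilities
    return fit, out


def classify_by_probability(probabilities, cutoff: float = 0.5):
    """pregnant iff posterior-mean probability >= cutoff (boundary inclusive)."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be inside (0, 1)")
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    return np.where(p >= cutoff, "pregnant", "non-pregnant")


def equal_odds_point(fit: LogisticFit) -> dict:
    """BP concentration (ng g^-1) at which pregnancy probability is 0.5.

    Per draw this is exp(-beta0/beta1); summarized by the posterior mean
    and central 95% credible interval. Errors out if slope draws straddle
    zero (the ratio is then unstable; report on the log-odds scale
    instead).
    """
    b0, b1 = fit.flat("beta0"), fit.flat("beta1")
    if b1.min() <= 0 <= b1.max():
        raise ValueError(
            "slope draws straddle 0; the equal-odds concentration is "
            "ill-defined — report the interval on the log scale instead"
        )
    conc = np.exp(-b0 / b1)
    lo, hi = np.percentile(conc, [2.5, 97.5])
    return {"mean": float(conc.mean()), "ci_low": float(lo), "ci_high": float(hi)}
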