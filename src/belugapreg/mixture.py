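"""Bayesian Gaussian mixtures on natural-log BP concentrations.

The working model: log-transformed blubber progesterone values y_i arise
from a K-component Gaussian mixture,

    y_i | z_i = k  ~  Normal(mu_k, sigma_k),      z_i ~ Categorical(w),

with weakly informative priors

    mu_k ~ Normal(0, 10),   sigma_k ~ Half-Normal(5),   w ~ Dirichlet(1).

On the log scale the plausible BP range spans roughly -2.3 (0.1 ng g^-1)
to 7.1 (1200 ng g^-1), so these priors cover it without favouring any
clustering. Inference is by Gibbs sampling: conjugate updates for the
allocations, means and weights, and a random-walk Metropolis step on
log sigma_k for the Half-Normal scale prior. Label switching is removed
exactly by relabelling components in ascending order of mean after every
sweep (a measure-preserving permutation of the symmetric posterior), so
every retained draw satisfies mu_1 < ... < mu_K and the highest-mean
component can be read as the pregnant cluster.

Model choice between K = 1, 2, 3 uses WAIC (variance form of the
effective-parameter penalty); convergence is monitored with the classic
Gelman-Rubin potential scale reduction factor across independent chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._rng import spawn_rng

__all__ = [
    "MCMCSettings",
    "MixtureFit",
    "fit_mixture",
    "select_mixture",
    "compute_waic",
    "gelman_rubin",
    "posterior_membership",
    "label_clusters",
    "ConvergenceWarning",
]

RHAT_THRESHOLD = 1.1

_PRIOR_MU_SD = 10.0
_PRIOR_SIGMA_SD = 5.0
_SIGMA_STEP = 0.25  # random-walk step on log sigma


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when any R-hat exceeds the 1.1 threshold."""


@dataclass(frozen=True)
class MCMCSettings:
    """Chain geometry for all MCMC fits.

    Defaults follow the full analysis protocol: 50 000 iterations of three
    independent chains, burn-in 10 000, thinning 40, leaving 1000 retained
    draws per chain. :meth:`scaled` gives a cheaper geometry with the same
    retained-draw count for tests and quick runs.
    """

    n_iterations: int = 50_000
    n_chains: int = 3
    thin: int = 40
    burn_in: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        kept = self.n_iterations - self.burn_in
        if kept <= 0 or kept % self.thin != 0:
            raise ValueError(
                "(n_iterations - burn_in) must be a positive multiple of thin"
            )
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @classmethod
    def scaled(cls, seed: int = 0, n_chains: int = 3) -> "MCMCSettings":
        """Reduced geometry (5000/1000/4) retaining 1000 draws per chain."""
        return cls(n_iterations=5000, n_chains=n_chains, thin=4, burn_in=1000, seed=seed)


@dataclass
class MixtureFit:
    """Posterior draws and diagnostics for one K-component mixture fit.

    Draw arrays have shape ``(n_chains, draws_per_chain, K)`` and satisfy
    the ascending-means identifiability constraint in every draw. The
    pregnant cluster is by construction the last (highest-mean) component.
    """

    K: int
    mu: np.ndarray
    sigma: np.ndarray
    w: np.ndarray
    log_lik: np.ndarray  # (n_chains, draws_per_chain, n_obs)
    rhat: dict = field(default_factory=dict)
    waic: float = np.nan
    settings: MCMCSettings | None = None
    n_obs: int = 0

    @property
    def pregnant_cluster(self) -> int:
        """Index of the highest-mean component (ascending order ⇒ last)."""
        return self.K - 1

    @property
    def converged(self) -> bool:
        return all(v < RHAT_THRESHOLD for v in self.rhat.values())

    def flat(self, name: str) -> np.ndarray:
        """Draws of ``mu``/``sigma``/``w`` flattened across chains: (S, K)."""
        arr = getattr(self, name)
        return arr.reshape(-1, arr.shape[-1])


def _log_norm_pdf(y, mu, sigma):
    return -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * ((y - mu) / sigma) ** 2


def _run_chain(y: np.ndarray, K: int, settings: MCMCSettings, chain: int):
    rng = spawn_rng(settings.seed, "mixture", K, chain)
    n = y.size
    draws = settings.draws_per_chain

    # overdispersed starts: means at jittered data quantiles
    q = np.quantile(y, (np.arange(K) + 0.5) / K)
    mu = np.sort(q + rng.normal(0, max(y.std(), 0.5) / 2, size=K))
    sigma = np.full(K, max(y.std(ddof=1) if n > 1 else 1.0, 0.2))
    w = np.full(K, 1.0 / K)

    mu_out = np.empty((draws, K))
    sigma_out = np.empty((draws, K))
    w_out = np.empty((draws, K))
    ll_out = np.empty((draws, n))

    prior_mu_prec = 1.0 / _PRIOR_MU_SD**2
    kept = 0
    for it in range(settings.n_iterations):
        # allocations via Gumbel-max on the log responsibilities
        logits = np.log(w)[None, :] + _log_norm_pdf(y[:, None], mu[None, :], sigma[None, :])
        if K > 1:
            z = np.argmax(logits + rng.gumbel(size=(n, K)), axis=1)
        else:
            z = np.zeros(n, dtype=int)

        n_k = np.bincount(z, minlength=K)
        sum_k = np.bincount(z, weights=y, minlength=K)

        # conjugate Normal update for means
        prec = prior_mu_prec + n_k / sigma**2
        mean = (sum_k / sigma**2) / prec
        mu = mean + rng.standard_normal(K) / np.sqrt(prec)

        # Metropolis on log sigma under the Half-Normal(5) prior
        sse = np.bincount(z, weights=(y - mu[z]) ** 2, minlength=K)
        log_sigma = np.log(sigma)
        prop = log_sigma + _SIGMA_STEP * rng.standard_normal(K)
        sig_p = np.exp(prop)

        def _logpost(s):
            # likelihood + Half-Normal prior + Jacobian of the log transform
            return (-n_k * np.log(s) - sse / (2 * s**2)
                    - s**2 / (2 * _PRIOR_SIGMA_SD**2) + np.log(s))

        accept = np.log(rng.uniform(size=K)) < _logpost(sig_p) - _logpost(sigma)
        sigma = np.where(accept, sig_p, sigma)

        # Dirichlet update for the weights
        if K > 1:
            w = rng.dirichlet(np.ones(K) + n_k)

        # exact relabelling: ascending means in every sweep
        order = np.argsort(mu)
        mu, sigma, w = mu[order], sigma[order], w[order]

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            mu_out[kept] = mu
            sigma_out[kept] = sigma
            w_out[kept] = w
            ll_out[kept] = logsumexp(
                np.log(w)[None, :] + _log_norm_pdf(y[:, None], mu[None, :], sigma[None, :]),
                axis=1,
            )
            kept += 1

    return mu_out, sigma_out, w_out, ll_out


def fit_mixture(log_values, K: int, settings: MCMCSettings) -> MixtureFit:
    """Fit a K-component Gaussian mixture to natural-log BP values by Gibbs.

    Returns retained draws (``draws_per_chain`` per chain after burn-in and
    thinning), per-parameter Gelman-Rubin diagnostics, and WAIC. Emits a
    :class:`ConvergenceWarning` if any R-hat exceeds 1.1 rather than
    failing silently. Deterministic for fixed settings (seed included).
    """
    y = np.asarray(log_values, dtype=float)
    if y.ndim != 1:
        raise ValueError("log_values must be 1-D")
    if not np.all(np.isfinite(y)):
        raise ValueError("log_values must be finite")
    if K < 1:
        raise ValueError("K must be >= 1")
    if y.size <= K:
        raise ValueError(f"need more than K={K} observations, got {y.size}")

    chains = [_run_chain(y, K, settings, c) for c in range(settings.n_chains)]
    mu = np.stack([c[0] for c in chains])
    sigma = np.stack([c[1] for c in chains])
    w = np.stack([c[2] for c in chains])
    ll = np.stack([c[3] for c in chains])

    fit = MixtureFit(K=K, mu=mu, sigma=sigma, w=w, log_lik=ll,
                     settings=settings, n_obs=y.size)

    if settings.n_chains >= 2:
        for k in range(K):
            fit.rhat[f"mu[{k}]"] = gelman_rubin(mu[:, :, k])
            fit.rhat[f"sigma[{k}]"] = gelman_rubin(sigma[:, :, k])
            if K > 1:
                fit.rhat[f"w[{k}]"] = gelman_rubin(w[:, :, k])
    fit.waic = compute_waic(fit, y)

    if not fit.converged:
        bad = {p: round(v, 3) for p, v in fit.rhat.items() if v >= RHAT_THRESHOLD}
        warnings.warn(
            f"K={K} mixture may not have converged; R-hat > {RHAT_THRESHOLD}: {bad}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return fit


def select_mixture(log_values, settings: MCMCSettings, ks=(1, 2, 3)):
    """Fit each candidate K and return ``(best_fit, {K: fit})`` by WAIC."""
    fits = {k: fit_mixture(log_values, k, settings) for k in ks}
    best = min(fits.values(), key=lambda f: f.waic)
    return best, fits


def compute_waic(fit: MixtureFit, log_values) -> float:
    """WAIC = -2 (lppd - p_waic2); lower is better.

    lppd is the summed log pointwise posterior-mean density and p_waic2 the
    summed posterior variance of the pointwise log densities, both over the
    retained draws. Recomputed from the draws, so identical inputs give
    identical values.
    """
    y = np.asarray(log_values, dtype=float)
    if y.size != fit.n_obs:
        raise ValueError(
            f"data length {y.size} does not match the {fit.n_obs} observations "
            "the fit was drawn for"
        )
    mu, sigma, w = fit.flat("mu"), fit.flat("sigma"), fit.flat("w")
    # (S, n): pointwise log density under every retained draw
    ll = logsumexp(
        np.log(w)[:, None, :]
        + _log_norm_pdf(y[None, :, None], mu[:, None, :], sigma[:, None, :]),
        axis=2,
    )
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic)


def gelman_rubin(chain_draws) -> float:
    """Classic potential scale reduction factor for one scalar parameter.

    ``chain_draws`` is (n_chains, n_draws). R-hat near 1 indicates the
    between-chain variance is consistent with the within-chain variance.
    Values below 1 arise only from the (n-1)/n shrinkage and carry no
    information, so the statistic is floored at 1 (exact copies give 1.0).
    """
    x = np.asarray(chain_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need draws from >= 2 chains of equal length")
    m, n = x.shape
    if n < 2:
        raise ValueError("chains must have length >= 2")
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(max(1.0, np.sqrt(var_hat / W)))


def posterior_membership(fit: MixtureFit, values) -> np.ndarray:
    """Posterior probability of each component for each BP value (ng g^-1).

    Responsibilities are computed per retained draw and averaged over
    draws; rows sum to 1. Values must be positive (log scale).
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if np.any(~(values > 0)):
        raise ValueError("BP values must be > 0")
    y = np.log(values)
    mu, sigma, w = fit.flat("mu"), fit.flat("sigma"), fit.flat("w")
    # (S, n, K) log responsibilities
    logr = np.log(w)[:, None, :] + _log_norm_pdf(
        y[None, :, None], mu[:, None, :], sigma[:, None, :]
    )
    logr = logr - logsumexp(logr, axis=2, keepdims=True)
    prob = np.exp(logr).mean(axis=0)
    return prob / prob.sum(axis=1, keepdims=True)


def label_clusters(fit: MixtureFit) -> list[str]:
    """Semantic labels per component, in ascending-mean order.

    The highest-mean component is the pregnant cluster; with three
    components the middle one is 'intermediate'; everything below is
    non-pregnant. A single component is undifferentiated (warns).
    """
    if fit.K == 1:
        warnings.warn("K=1: single undifferentiated component", stacklevel=2)
        return ["undifferentiated"]
    if fit.K == 2:
        return ["non-pregnant", "pregnant"]
    return ["non-pregnant"] + ["intermediate"] * (fit.K - 2) + ["pregnant"]
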