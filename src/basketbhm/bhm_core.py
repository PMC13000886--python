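"""Bayesian hierarchical models for subtrial-specific treatment effects.

Three data models share one hierarchical parameter model.  Writing
``Y_ik`` for the outcome of patient ``i`` in subtrial ``k``, ``T_ik`` for
the 0/1 treatment indicator and ``X_ik`` for (cluster-centered) baseline
covariates:

* unadjusted:       ``E(Y) = alpha_k + theta_k T``
* ANCOVA I:         ``E(Y) = alpha_k + theta_k T + beta_k' X``
* ANCOVA II:        ``E(Y) = alpha_k + theta_k T + beta_k' X + gamma_k' (T X)``

with normal outcome noise of shared variance ``sigma_y^2``.  The
subtrial effects are exchangeable,

    theta_k | mu_theta, sigma_theta ~ N(mu_theta, sigma_theta^2),
    mu_theta ~ N(0, v_coef),      sigma_theta ~ half-t(s_HT, d),

so information is borrowed across subtrials with strength governed by
``sigma_theta``; a larger half-t scale ``s_HT`` means less borrowing.
All remaining coefficients carry independent N(0, v_coef) priors and the
outcome variance an inverse-gamma prior.

The normal-outcome posterior is sampled by a blocked Gibbs sampler (all
conditionals conjugate; see :mod:`basketbhm._gibbs`).  A Bernoulli
outcome variant with a logistic link replaces the coefficient-block
updates with adaptive Metropolis steps and is used for binary-endpoint
sensitivity analyses; complete separation within a subtrial manifests as
divergent coefficient draws and is flagged rather than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._gibbs import gibbs_normal
from .trial_data import BasketTrialData

__all__ = [
    "BhmSpec",
    "McmcConfig",
    "PosteriorDraws",
    "EffectEstimate",
    "ScalarSummary",
    "FitError",
    "fit_bhm",
    "summarize_posterior",
    "decide_rejection",
    "estimate_overall_effect",
    "bhm_spec_from_yaml",
    "mcmc_config_from_yaml",
]

DATA_MODELS = ("UNADJUSTED", "ANCOVA1", "ANCOVA2")


class FitError(RuntimeError):
    """Raised when a model cannot be fitted to the supplied data."""


@dataclass(frozen=True)
class BhmSpec:
    """Model variant and hyperparameters.

    ``v_coef`` is the prior variance (not SD) of the normal priors on
    intercepts, covariate coefficients and the population mean
    ``mu_theta``; the default N(0, 100) is weakly informative on the
    outcome scale of the benchmark scenarios.  ``sigma_ht`` and ``df``
    parameterize the half-t prior on ``sigma_theta``: HT(2, 5) gives the
    default degree of borrowing, HT(100, 5) is near-flat (little
    borrowing).  ``a_y``/``b_y`` are the inverse-gamma shape/scale on
    ``sigma_y^2`` (prior mean ``b_y/(a_y-1)`` = 20 at the defaults).

    ``fixed_sigma_theta`` / ``fixed_sigma_y2`` clamp the corresponding
    parameter at a point mass — degenerate priors used to validate the
    sampler against exact posteriors.
    """

    data_model: str = "UNADJUSTED"
    outcome_model: str = "normal"
    v_coef: float = 100.0
    sigma_ht: float = 2.0
    df: float = 5.0
    a_y: float = 2.0
    b_y: float = 20.0
    fixed_sigma_theta: float | None = None
    fixed_sigma_y2: float | None = None
    interval_method: str = "symmetric_mass"  # or "normal" for mean +/- z*SD

    def __post_init__(self):
        if self.data_model not in DATA_MODELS:
            raise ValueError(f"data_model must be one of {DATA_MODELS}")
        if self.outcome_model not in ("normal", "logistic"):
            raise ValueError("outcome_model must be 'normal' or 'logistic'")
        for name in ("v_coef", "sigma_ht", "df", "a_y", "b_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.interval_method not in ("symmetric_mass", "normal"):
            raise ValueError("interval_method must be 'symmetric_mass' or 'normal'")


@dataclass(frozen=True)
class McmcConfig:
    """Chain control: total length, burn-in discarded from the front, seed."""

    n_iter: int = 10_000
    burn_in: int = 2_000
    seed: int = 0
    thin: int = 1

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MCMC draws.

    ``coef`` has shape (draws, K, p) with columns ordered
    (alpha_k, theta_k, beta_k..., gamma_k...); ``theta`` is the view of
    the treatment column.
    """

    coef: np.ndarray
    coef_names: tuple[str, ...]
    mu_theta: np.ndarray
    sigma_theta: np.ndarray
    sigma_y2: np.ndarray | None
    spec: BhmSpec
    mcmc: McmcConfig
    converged: bool = True

    @property
    def theta(self) -> np.ndarray:
        return self.coef[:, :, 1]

    @property
    def K(self) -> int:
        return self.coef.shape[1]

    @property
    def n_draws(self) -> int:
        return self.coef.shape[0]

    def to_frame(self):
        """Columnar view of the retained draws (one row per iteration)."""
        import pandas as pd

        cols = {"mu_theta": self.mu_theta, "sigma_theta": self.sigma_theta}
        if self.sigma_y2 is not None:
            cols["sigma_y2"] = self.sigma_y2
        for k in range(self.K):
            for j, name in enumerate(self.coef_names):
                cols[f"{name}_{k + 1}"] = self.coef[:, k, j]
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class EffectEstimate:
    """Per-subtrial point estimates with SEs and 95% intervals."""

    method: str
    estimate: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95
    converged: bool = True
    overall: "ScalarSummary | None" = None

    def __post_init__(self):
        for name in ("estimate", "se", "lower", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        ok = np.isnan(self.estimate) | (
            (self.lower <= self.estimate + 1e-12) & (self.estimate <= self.upper + 1e-12)
        )
        if not ok.all():
            raise ValueError("interval must contain the point estimate")

    @property
    def K(self) -> int:
        return self.estimate.shape[0]


@dataclass(frozen=True)
class ScalarSummary:
    """Posterior summary of a scalar parameter (e.g. the overall effect)."""

    mean: float
    sd: float
    lower: float
    upper: float
    level: float = 0.95


# --------------------------------------------------------------------------
# design construction

def build_design(data: BasketTrialData, data_model: str) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix with columns (1, T, X..., T*X...) per the data model."""
    n = data.n
    cols = [np.ones(n), data.treatment.astype(float)]
    names = ["alpha", "theta"]
    if data_model in ("ANCOVA1", "ANCOVA2"):
        for j in range(data.p):
            cols.append(data.covariates[:, j])
            names.append(f"beta{j + 1}")
    if data_model == "ANCOVA2":
        for j in range(data.p):
            cols.append(data.treatment * data.covariates[:, j])
            names.append(f"gamma{j + 1}")
    return np.column_stack(cols), tuple(names)


def _check_centered(data: BasketTrialData, tol: float = 1e-8) -> bool:
    for k in range(1, data.K + 1):
        m = data.mask(k)
        if m.any() and np.abs(data.covariates[m].mean(axis=0)).max() > tol:
            return False
    return True


def _sufficient_stats(data: BasketTrialData, X: np.ndarray):
    K = data.K
    p = X.shape[1]
    xtx = np.zeros((K, p, p))
    xty = np.zeros((K, p))
    yty = np.zeros(K)
    for k in range(1, K + 1):
        m = data.mask(k)
        Xk, yk = X[m], data.outcome[m]
        xtx[k - 1] = Xk.T @ Xk
        xty[k - 1] = Xk.T @ yk
        yty[k - 1] = yk @ yk
        if m.sum() and np.linalg.matrix_rank(Xk) < p:
            raise FitError(
                f"design matrix is rank-deficient (collinear) within subtrial {k}"
            )
    return xtx, xty, yty


# --------------------------------------------------------------------------
# fitting

def fit_bhm(
    data: BasketTrialData,
    spec: BhmSpec,
    mcmc: McmcConfig,
    *,
    allow_uncentered: bool = False,
    prior_only: bool = False,
) -> PosteriorDraws:
    """Draw from the posterior of the specified hierarchical model.

    Adjusted fits require cluster-centered covariates so that ``theta_k``
    keeps the subtrial-average-treatment-effect interpretation; pass
    ``allow_uncentered=True`` to override.  ``prior_only=True`` zeroes the
    likelihood contribution (an empty design), so the chain samples the
    prior — a validation hook.
    """
    if spec.data_model != "UNADJUSTED":
        if data.p == 0:
            raise FitError(f"{spec.data_model} requires at least one covariate column")
        if not prior_only and not allow_uncentered and not _check_centered(data):
            raise FitError(
                "covariates are not cluster-centered; center_covariates() first "
                "or pass allow_uncentered=True"
            )

    X, names = build_design(data, spec.data_model)
    if spec.outcome_model == "logistic":
        return _fit_logistic(data, X, names, spec, mcmc, prior_only)

    if prior_only:
        K, p = data.K, X.shape[1]
        xtx = np.zeros((K, p, p))
        xty = np.zeros((K, p))
        yty = np.zeros(K)
        n_total = 0
    else:
        xtx, xty, yty = _sufficient_stats(data, X)
        n_total = data.n

    coef, mu, sig_t, sig_y2 = gibbs_normal(
        xtx, xty, yty, n_total, 1,
        spec.v_coef, spec.sigma_ht, spec.df, spec.a_y, spec.b_y,
        spec.fixed_sigma_theta**2 if spec.fixed_sigma_theta else -1.0,
        spec.fixed_sigma_y2 if spec.fixed_sigma_y2 else -1.0,
        mcmc.n_iter, mcmc.burn_in, mcmc.thin, np.uint32(mcmc.seed & 0x7FFFFFFF),
    )
    return PosteriorDraws(
        coef=coef, coef_names=names, mu_theta=mu, sigma_theta=sig_t,
        sigma_y2=sig_y2, spec=spec, mcmc=mcmc, converged=True,
    )


def _fit_logistic(data, X, names, spec, mcmc, prior_only):
    """Metropolis-within-Gibbs for the Bernoulli/logistic data model.

    Coefficient blocks are updated by a random-walk proposal whose scale
    adapts toward ~30% acceptance during burn-in only (frozen afterwards
    to preserve detailed balance); the hierarchy updates stay conjugate.
    """
    rng = np.random.default_rng(mcmc.seed)
    K, p = data.K, X.shape[1]
    theta_idx = 1
    masks = [data.mask(k) for k in range(1, K + 1)]
    Xs = [X[m] for m in masks]
    ys = [data.outcome[m] for m in masks]
    if prior_only:
        Xs = [Xk[:0] for Xk in Xs]
        ys = [yk[:0] for yk in ys]

    # proposal shape from the logistic Fisher-information bound X'X/4
    prop_chol = []
    for k in range(K):
        info = Xs[k].T @ Xs[k] / 4.0 + np.eye(p) / spec.v_coef
        prop_chol.append(np.linalg.cholesky(np.linalg.inv(info)))
    log_step = np.zeros(K)

    coef = np.zeros((K, p))
    mu_theta, sigma_theta2, aux = 0.0, 1.0, 1.0
    if spec.fixed_sigma_theta:
        sigma_theta2 = spec.fixed_sigma_theta**2

    def loglik(k, b):
        lp = Xs[k] @ b
        return ys[k] @ lp - np.logaddexp(0.0, lp).sum()

    def logprior(k, b):
        out = -0.5 * (b[theta_idx] - mu_theta) ** 2 / sigma_theta2
        for j in range(p):
            if j != theta_idx:
                out -= 0.5 * b[j] ** 2 / spec.v_coef
        return out

    curr_ll = np.array([loglik(k, coef[k]) for k in range(K)])
    n_keep = mcmc.n_retained
    out_coef = np.empty((n_keep, K, p))
    out_mu = np.empty(n_keep)
    out_sig = np.empty(n_keep)
    kept = 0
    for it in range(mcmc.n_iter):
        for k in range(K):
            prop = coef[k] + np.exp(log_step[k]) * (prop_chol[k] @ rng.standard_normal(p))
            ll_prop = loglik(k, prop)
            log_acc = ll_prop + logprior(k, prop) - curr_ll[k] - logprior(k, coef[k])
            accepted = np.log(rng.random()) < log_acc
            if accepted:
                coef[k] = prop
                curr_ll[k] = ll_prop
            if it < mcmc.burn_in:
                log_step[k] += (float(accepted) - 0.3) / np.sqrt(it + 1.0)

        sum_theta = coef[:, theta_idx].sum()
        prec_mu = K / sigma_theta2 + 1.0 / spec.v_coef
        mu_theta = (sum_theta / sigma_theta2) / prec_mu + rng.standard_normal() / np.sqrt(prec_mu)
        if not spec.fixed_sigma_theta:
            ss = ((coef[:, theta_idx] - mu_theta) ** 2).sum()
            sigma_theta2 = (spec.df / aux + 0.5 * ss) / rng.gamma(0.5 * (spec.df + K))
            aux = (spec.df / sigma_theta2 + 1.0 / spec.sigma_ht**2) / rng.gamma(0.5 * (spec.df + 1))

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            out_coef[kept] = coef
            out_mu[kept] = mu_theta
            out_sig[kept] = np.sqrt(sigma_theta2)
            kept += 1

    converged = not _diverging(out_coef)
    return PosteriorDraws(
        coef=out_coef, coef_names=names, mu_theta=out_mu, sigma_theta=out_sig,
        sigma_y2=None, spec=spec, mcmc=mcmc, converged=converged,
    )


def _diverging(coef_draws: np.ndarray, hard_limit: float = 30.0) -> bool:
    """Heuristic separation detector: monotone drift or huge coefficients.

    Under 0-1 separation the likelihood is monotone in some coefficient
    direction, so its draws drift outward instead of mixing.
    """
    if np.abs(coef_draws).max() > hard_limit:
        return True
    n = coef_draws.shape[0]
    if n < 8:
        return False
    quarters = np.array_split(np.abs(coef_draws).max(axis=(1, 2)), 4)
    means = np.array([q.mean() for q in quarters])
    return bool(np.all(np.diff(means) > 0) and means[-1] > 10.0 and means[-1] > 2 * means[0])


# --------------------------------------------------------------------------
# summaries and decisions

def _symmetric_halfwidth(draws: np.ndarray, center: float, level: float) -> float:
    """Smallest h with at least ``level`` of draws inside [center-h, center+h]."""
    dev = np.sort(np.abs(draws - center))
    m = int(np.ceil(level * dev.shape[0]))
    return float(dev[max(m - 1, 0)])


def _summarize_draws(draws: np.ndarray, level: float, method: str) -> tuple[float, float, float, float]:
    mean = float(draws.mean())
    sd = float(draws.std(ddof=1)) if draws.shape[0] > 1 else 0.0
    if method == "normal":
        from scipy.stats import norm

        h = norm.ppf(0.5 + level / 2.0) * sd
    else:
        h = _symmetric_halfwidth(draws, mean, level)
    return mean, sd, mean - h, mean + h


def summarize_posterior(
    draws: PosteriorDraws, level: float = 0.95, method_label: str | None = None
) -> EffectEstimate:
    """Posterior means with credible intervals symmetric about the mean.

    The interval is the empirical symmetric-mass interval: the smallest
    half-width ``h`` such that at least ``level`` of the retained draws
    fall in ``[mean - h, mean + h]`` (a normal approximation
    ``mean +/- z*SD`` is available through ``BhmSpec.interval_method``).
    """
    if draws.n_draws == 0:
        raise ValueError("no retained draws to summarize")
    if draws.n_draws < 1000:
        warnings.warn(
            f"only {draws.n_draws} retained draws; posterior summaries may be noisy",
            stacklevel=2,
        )
    interval = draws.spec.interval_method
    est = np.empty(draws.K)
    se = np.empty(draws.K)
    lo = np.empty(draws.K)
    hi = np.empty(draws.K)
    for k in range(draws.K):
        est[k], se[k], lo[k], hi[k] = _summarize_draws(draws.theta[:, k], level, interval)
    overall = estimate_overall_effect(draws, level)
    label = method_label or f"{draws.spec.data_model}-BHM"
    return EffectEstimate(
        method=label, estimate=est, se=se, lower=lo, upper=hi,
        level=level, converged=draws.converged, overall=overall,
    )


def decide_rejection(est: EffectEstimate, null_value: float = 0.0) -> np.ndarray:
    """Reject H0k iff the (closed) interval excludes the null value."""
    return (null_value < est.lower) | (null_value > est.upper)


def estimate_overall_effect(draws: PosteriorDraws, level: float = 0.95) -> ScalarSummary:
    """Summary of the population mean effect ``mu_theta`` (overall efficacy)."""
    mean, sd, lo, hi = _summarize_draws(
        draws.mu_theta, level, draws.spec.interval_method
    )
    return ScalarSummary(mean=mean, sd=sd, lower=lo, upper=hi, level=level)


def bhm_spec_from_yaml(path) -> BhmSpec:
    """Load a :class:`BhmSpec` from a YAML mapping of its field names."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return BhmSpec(**raw)


def mcmc_config_from_yaml(path) -> McmcConfig:
    """Load a :class:`McmcConfig` from a YAML mapping of its field names."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return McmcConfig(**raw)
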