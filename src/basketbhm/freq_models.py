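"""Frequentist comparators: stratified and random-effect AN(C)OVA.

Stratified models fit ordinary least squares separately within each
subtrial on the unadjusted / ANCOVA I / ANCOVA II mean structure, with
classical residual-variance standard errors and t-based confidence
intervals — the no-borrowing reference analyses.

Random-effect models fit one linear mixed model across subtrials with a
random intercept and a random treatment slope at the subtrial level
(unstructured 2x2 covariance), estimated by REML through
``statsmodels.MixedLM``.  Covariate terms enter as subtrial-specific
fixed effects.  The subtrial-specific treatment effect is the fixed
treatment coefficient plus the predicted (BLUP) random slope; its SE
combines the fixed-coefficient variance with the BLUP conditional
variance.  With only a handful of subtrials the variance components are
weakly identified, so optimizer failure and boundary (singular)
estimates are reported through a convergence flag rather than an
exception; nonconverged fits carry no intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bhm_core import EffectEstimate, FitError, build_design
from .trial_data import BasketTrialData

__all__ = ["FreqSpec", "fit_stratified", "fit_random_effects"]

ADJUSTMENTS = ("NONE", "ANCOVA1", "ANCOVA2")


@dataclass(frozen=True)
class FreqSpec:
    family: str = "STRATIFIED"  # or "RANDOM_EFFECT"
    adjustment: str = "NONE"    # "NONE" | "ANCOVA1" | "ANCOVA2"
    level: float = 0.95

    def __post_init__(self):
        if self.family not in ("STRATIFIED", "RANDOM_EFFECT"):
            raise ValueError("family must be STRATIFIED or RANDOM_EFFECT")
        if self.adjustment not in ADJUSTMENTS:
            raise ValueError(f"adjustment must be one of {ADJUSTMENTS}")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")

    @property
    def data_model(self) -> str:
        return "UNADJUSTED" if self.adjustment == "NONE" else self.adjustment

    @property
    def label(self) -> str:
        suffix = {"NONE": "ANOVA", "ANCOVA1": "ANCOVAI", "ANCOVA2": "ANCOVAII"}[self.adjustment]
        return ("s" if self.family == "STRATIFIED" else "re") + suffix


def fit_stratified(data: BasketTrialData, spec: FreqSpec) -> EffectEstimate:
    """Per-subtrial OLS on the requested mean structure.

    The treatment-effect estimate is the coefficient of T; its SE uses
    the classical unbiased residual-variance estimator and the interval a
    t critical value with the per-subtrial residual degrees of freedom.
    """
    X, _ = build_design(data, spec.data_model)
    p = X.shape[1]
    K = data.K
    est = np.empty(K)
    se = np.empty(K)
    lo = np.empty(K)
    hi = np.empty(K)
    for k in range(1, K + 1):
        m = data.mask(k)
        Xk, yk = X[m], data.outcome[m]
        nk = Xk.shape[0]
        if nk <= p:
            raise FitError(
                f"subtrial {k} has {nk} patients but the model needs more than {p}"
            )
        if np.linalg.matrix_rank(Xk) < p:
            raise FitError(f"design matrix is rank-deficient within subtrial {k}")
        xtx_inv = np.linalg.inv(Xk.T @ Xk)
        beta = xtx_inv @ (Xk.T @ yk)
        resid = yk - Xk @ beta
        dof = nk - p
        s2 = resid @ resid / dof
        est[k - 1] = beta[1]
        se[k - 1] = np.sqrt(s2 * xtx_inv[1, 1])
        tcrit = stats.t.ppf(0.5 + spec.level / 2.0, dof)
        lo[k - 1] = est[k - 1] - tcrit * se[k - 1]
        hi[k - 1] = est[k - 1] + tcrit * se[k - 1]
    return EffectEstimate(
        method=spec.label, estimate=est, se=se, lower=lo, upper=hi,
        level=spec.level, converged=True,
    )


def _re_design(data: BasketTrialData, adjustment: str) -> np.ndarray:
    """Fixed-effect design: intercept, T, then per-subtrial covariate terms."""
    n, K = data.n, data.K
    cols = [np.ones(n), data.treatment.astype(float)]
    if adjustment in ("ANCOVA1", "ANCOVA2"):
        for j in range(data.p):
            for k in range(1, K + 1):
                cols.append(data.covariates[:, j] * (data.subtrial == k))
    if adjustment == "ANCOVA2":
        for j in range(data.p):
            for k in range(1, K + 1):
                cols.append(
                    data.treatment * data.covariates[:, j] * (data.subtrial == k)
                )
    return np.column_stack(cols)


def fit_random_effects(data: BasketTrialData, spec: FreqSpec) -> EffectEstimate:
    """Linear mixed model with random intercept and random treatment slope.

    Returns NaN estimates/intervals with ``converged=False`` when the
    optimizer fails or the random-effect covariance is singular (a
    boundary estimate), which is common for small numbers of subtrials.
    """
    import statsmodels.api as sm

    if data.K < 2:
        raise FitError("random-effect models require at least 2 subtrials")
    exog = _re_design(data, spec.data_model if spec.adjustment != "NONE" else "NONE")
    exog_re = np.column_stack([np.ones(data.n), data.treatment.astype(float)])

    # REML variance components are often at the boundary with few subtrials
    # (a zero variance component is a legitimate estimate here); convergence
    # means the optimizer converged on some method of the retry ladder.
    model = sm.MixedLM(data.outcome, exog, groups=data.subtrial, exog_re=exog_re)
    result, converged = None, False
    for method in ("bfgs", "lbfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                candidate = model.fit(reml=True, method=method)
        except (np.linalg.LinAlgError, ValueError):
            continue
        result = candidate
        if candidate.converged:
            converged = True
            break

    K = data.K
    est = np.empty(K)
    se = np.empty(K)
    if converged:
        try:
            fixed_t = result.params[1]
            var_fixed_t = result.cov_params()[1, 1]
            blups = result.random_effects
            blup_cov = result.random_effects_cov
            for k in range(1, K + 1):
                slope = np.asarray(blups[k])[1]
                cond_var = max(float(np.asarray(blup_cov[k])[1, 1]), 0.0)
                est[k - 1] = fixed_t + slope
                se[k - 1] = np.sqrt(var_fixed_t + cond_var)
        except (np.linalg.LinAlgError, ValueError, KeyError):
            converged = False
    if not converged:
        nan = np.full(K, np.nan)
        return EffectEstimate(
            method=spec.label, estimate=nan, se=nan.copy(), lower=nan.copy(),
            upper=nan.copy(), level=spec.level, converged=False,
        )
    z = stats.norm.ppf(0.5 + spec.level / 2.0)
    return EffectEstimate(
        method=spec.label, estimate=est, se=se, lower=est - z * se,
        upper=est + z * se, level=spec.level, converged=True,
    )
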