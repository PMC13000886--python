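"""Independent reference computations used to validate the samplers.

Everything here deliberately avoids the code paths under test: OLS via
pseudo-inverse, posteriors via dense-grid quadrature or closed-form
Gaussian marginalization, variance components via method of moments.
"""

import numpy as np
from scipy import stats


def pinv_ols(X, y):
    """Normal-equations solution via pseudo-inverse."""
    return np.linalg.pinv(X) @ y


def _log_marginal_alpha(y_resid, sigma_y2, v_alpha):
    """log N(y_resid; 0, v_alpha * 11' + sigma_y2 * I) (intercept integrated out)."""
    n = y_resid.shape[0]
    cov = v_alpha * np.ones((n, n)) + sigma_y2 * np.eye(n)
    return stats.multivariate_normal.logpdf(y_resid, mean=np.zeros(n), cov=cov)


def grid_posterior_two_subtrials(
    y, t, subtrial, sigma_theta, sigma_y2, v_coef=100.0, n_grid=121, half_width=8.0
):
    """Dense-grid posterior for the unadjusted 2-subtrial hierarchical model
    with fixed (point-mass) sigma_theta and sigma_y2.

    Intercepts are integrated out analytically per subtrial; the grid runs
    over (theta_1, theta_2, mu_theta).  Returns posterior means and SDs of
    (theta_1, theta_2).
    """
    sigma_theta2 = sigma_theta**2
    ks = np.unique(subtrial)
    assert ks.shape[0] == 2
    # data-informed grid centers from per-subtrial arm-mean differences
    centers = []
    for k in ks:
        m = subtrial == k
        centers.append(y[m][t[m] == 1].mean() - y[m][t[m] == 0].mean())
    grids = [c + np.linspace(-half_width, half_width, n_grid) for c in centers]
    mu_grid = np.linspace(
        min(centers) - half_width, max(centers) + half_width, n_grid
    )

    # 1-D profiles of the alpha-integrated likelihood per subtrial
    log_m = []
    for k, grid in zip(ks, grids):
        m = subtrial == k
        vals = np.array(
            [_log_marginal_alpha(y[m] - th * t[m], sigma_y2, v_coef) for th in grid]
        )
        log_m.append(vals)

    th1 = grids[0][:, None, None]
    th2 = grids[1][None, :, None]
    mu = mu_grid[None, None, :]
    log_post = (
        log_m[0][:, None, None]
        + log_m[1][None, :, None]
        - 0.5 * (th1 - mu) ** 2 / sigma_theta2
        - 0.5 * (th2 - mu) ** 2 / sigma_theta2
        - 0.5 * mu**2 / v_coef
    )
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    out = []
    for axis, grid in ((0, grids[0]), (1, grids[1])):
        marg = w.sum(axis=tuple(a for a in (0, 1, 2) if a != axis))
        mean = (marg * grid).sum()
        sd = np.sqrt((marg * (grid - mean) ** 2).sum())
        out.append((mean, sd))
    return out  # [(mean1, sd1), (mean2, sd2)]


def conjugate_single_subtrial(y, t, v_alpha=100.0, v_theta=1e10, a_y=2.0, b_y=20.0,
                              n_grid=400):
    """Reference posterior mean/SD of theta for one subtrial, unadjusted model,
    near-flat theta prior, by 1-D quadrature over the outcome variance.

    Given sigma_y2, the coefficient posterior is exact multivariate normal;
    sigma_y2 is integrated over a log-spaced grid weighted by the closed-form
    Gaussian marginal likelihood times its inverse-gamma prior.
    """
    X = np.column_stack([np.ones_like(y), t.astype(float)])
    prec0 = np.diag([1.0 / v_alpha, 1.0 / v_theta])
    s2_grid = np.exp(np.linspace(np.log(1e-3), np.log(1e3), n_grid))
    log_w = np.empty(n_grid)
    means = np.empty(n_grid)
    vars_ = np.empty(n_grid)
    n = y.shape[0]
    for i, s2 in enumerate(s2_grid):
        # Gaussian evidence in coefficient space (stable for near-flat priors)
        prec_n = X.T @ X / s2 + prec0
        cov_b = np.linalg.inv(prec_n)
        mean_b = cov_b @ (X.T @ y / s2)
        log_evidence = (
            -0.5 * n * np.log(2 * np.pi * s2)
            + 0.5 * np.linalg.slogdet(prec0)[1]
            - 0.5 * np.linalg.slogdet(prec_n)[1]
            - 0.5 * (y @ y / s2 - mean_b @ prec_n @ mean_b)
        )
        log_w[i] = (
            log_evidence
            + stats.invgamma.logpdf(s2, a_y, scale=b_y)
            + np.log(s2)  # log-spaced grid jacobian
        )
        means[i] = mean_b[1]
        vars_[i] = cov_b[1, 1]
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    mean = (w * means).sum()
    var = (w * (vars_ + means**2)).sum() - mean**2
    return mean, np.sqrt(var)


def moment_variance_components(estimates, arm_variance):
    """Method-of-moments estimate of the random-slope variance.

    ``estimates`` are per-subtrial treatment-effect OLS estimates; their
    sampling variance is tau^2 + arm_variance, so
    tau^2_hat = Var(estimates) - arm_variance.
    """
    return np.var(estimates, ddof=1) - arm_variance
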