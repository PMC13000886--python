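"""Blocked Gibbs kernel for the normal-outcome hierarchical models.

The sampler works entirely on per-subtrial sufficient statistics
(``X'X``, ``X'y``, ``y'y``), so one iteration costs a handful of small
dense solves regardless of the number of patients.  The half-t prior on
the between-subtrial scale is represented by the standard inverse-gamma
scale mixture, which keeps every update conjugate:

    sigma_theta^2 | a ~ InvGamma(d/2, d/a),   a ~ InvGamma(1/2, 1/s_HT^2)
    =>  sigma_theta ~ half-t(scale=s_HT, df=d).

Point-mass (degenerate) priors on sigma_theta^2 and sigma_y^2 are
supported through the ``fixed_*`` arguments (pass a negative value to
sample them); they exist so the sampler can be validated against exact
dense-grid posteriors.
"""

import numpy as np
from numba import njit

__all__ = ["gibbs_normal"]


@njit(cache=True)
def _inv_gamma(shape, scale):
    # scale / Gamma(shape, 1) ~ InvGamma(shape, scale)
    return scale / np.random.gamma(shape, 1.0)


@njit(cache=True)
def gibbs_normal(
    xtx,            # (K, p, p) per-subtrial X'X
    xty,            # (K, p)    per-subtrial X'y
    yty,            # (K,)      per-subtrial y'y
    n_total,        # total patient count
    theta_idx,      # column of the treatment coefficient in the design
    v_coef,         # prior variance of alpha/beta/gamma and of mu_theta
    sigma_ht,       # half-t scale for sigma_theta
    df_ht,          # half-t degrees of freedom
    a_y,            # inverse-gamma shape for sigma_y^2
    b_y,            # inverse-gamma scale for sigma_y^2
    fixed_sigma_theta2,  # >0: hold sigma_theta^2 at this value
    fixed_sigma_y2,      # >0: hold sigma_y^2 at this value
    n_iter,
    burn_in,
    thin,
    seed,
):
    np.random.seed(seed)
    K, p = xty.shape

    coef = np.zeros((K, p))
    mu_theta = 0.0
    sigma_theta2 = fixed_sigma_theta2 if fixed_sigma_theta2 > 0 else 1.0
    sigma_y2 = fixed_sigma_y2 if fixed_sigma_y2 > 0 else 1.0
    aux = 1.0

    n_keep = (n_iter - burn_in + thin - 1) // thin
    out_coef = np.empty((n_keep, K, p))
    out_mu = np.empty(n_keep)
    out_sigma_theta = np.empty(n_keep)
    out_sigma_y2 = np.empty(n_keep)

    kept = 0
    for it in range(n_iter):
        # --- per-subtrial coefficient blocks (joint multivariate-normal draw)
        for k in range(K):
            prec = xtx[k] / sigma_y2
            bvec = xty[k] / sigma_y2
            for j in range(p):
                if j == theta_idx:
                    prec[j, j] += 1.0 / sigma_theta2
                    bvec[j] += mu_theta / sigma_theta2
                else:
                    prec[j, j] += 1.0 / v_coef
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, bvec)
            z = np.random.standard_normal(p)
            coef[k] = mean + np.linalg.solve(chol.T, z)

        # --- population mean of the treatment effects
        sum_theta = 0.0
        for k in range(K):
            sum_theta += coef[k, theta_idx]
        prec_mu = K / sigma_theta2 + 1.0 / v_coef
        mean_mu = (sum_theta / sigma_theta2) / prec_mu
        mu_theta = mean_mu + np.random.standard_normal() / np.sqrt(prec_mu)

        # --- between-subtrial variance (half-t via scale mixture)
        if fixed_sigma_theta2 <= 0:
            ss = 0.0
            for k in range(K):
                d = coef[k, theta_idx] - mu_theta
                ss += d * d
            sigma_theta2 = _inv_gamma(0.5 * (df_ht + K), df_ht / aux + 0.5 * ss)
            aux = _inv_gamma(0.5 * (df_ht + 1.0), df_ht / sigma_theta2 + 1.0 / (sigma_ht * sigma_ht))

        # --- outcome variance
        if fixed_sigma_y2 <= 0:
            ssr = 0.0
            for k in range(K):
                bk = coef[k]
                quad = 0.0
                lin = 0.0
                for i in range(p):
                    lin += bk[i] * xty[k, i]
                    for j in range(p):
                        quad += bk[i] * xtx[k, i, j] * bk[j]
                ssr += yty[k] - 2.0 * lin + quad
            if ssr < 0.0:
                ssr = 0.0
            sigma_y2 = _inv_gamma(a_y + 0.5 * n_total, b_y + 0.5 * ssr)

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_coef[kept] = coef
            out_mu[kept] = mu_theta
            out_sigma_theta[kept] = np.sqrt(sigma_theta2)
            out_sigma_y2[kept] = sigma_y2
            kept += 1

    return out_coef, out_mu, out_sigma_theta, out_sigma_y2
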