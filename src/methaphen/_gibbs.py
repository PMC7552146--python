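"""Numba kernels: single-site Gibbs scans over mixed-model location effects.

The coefficient structure is the standard mixed-model system for
y = Xb + Z1 h + Z2 a + e with W = [X Z1 Z2].  One scan updates every
location effect from its full conditional given the current variances.
Normal deviates are pre-generated by the caller so that all randomness
flows from one seeded generator.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _scan_uni(indptr, indices, data, wty, ai_indptr, ai_indices, ai_data,
              off_h, off_a, sigma_e2, sigma_h2, sigma_a2, theta, z):
    m = theta.shape[0]
    for j in range(m):
        s_lik = 0.0
        c_lik = 0.0
        for idx in range(indptr[j], indptr[j + 1]):
            k = indices[idx]
            if k == j:
                c_lik = data[idx]
            else:
                s_lik += data[idx] * theta[k]
        rhs = (wty[j] - s_lik) / sigma_e2
        cjj = c_lik / sigma_e2
        if off_h <= j < off_a:
            cjj += 1.0 / sigma_h2
        elif j >= off_a:
            ja = j - off_a
            s_pr = 0.0
            d_pr = 0.0
            for idx in range(ai_indptr[ja], ai_indptr[ja + 1]):
                k = ai_indices[idx]
                if k == ja:
                    d_pr = ai_data[idx]
                else:
                    s_pr += ai_data[idx] * theta[off_a + k]
            rhs -= s_pr / sigma_a2
            cjj += d_pr / sigma_a2
        theta[j] = rhs / cjj + z[j] / np.sqrt(cjj)


@njit(cache=True)
def _scan_biv(indptr, indices, data, wty, ai_indptr, ai_indices, ai_data,
              off_h, off_a, rinv, ginv, hinv, theta, z):
    """theta, wty, z are (m, 2); rinv/ginv/hinv are 2x2 precisions."""
    m = theta.shape[0]
    for j in range(m):
        s0 = 0.0
        s1 = 0.0
        c_lik = 0.0
        for idx in range(indptr[j], indptr[j + 1]):
            k = indices[idx]
            v = data[idx]
            if k == j:
                c_lik = v
            else:
                s0 += v * theta[k, 0]
                s1 += v * theta[k, 1]
        r0 = wty[j, 0] - s0
        r1 = wty[j, 1] - s1
        rhs0 = rinv[0, 0] * r0 + rinv[0, 1] * r1
        rhs1 = rinv[1, 0] * r0 + rinv[1, 1] * r1
        p00 = c_lik * rinv[0, 0]
        p01 = c_lik * rinv[0, 1]
        p11 = c_lik * rinv[1, 1]
        if off_h <= j < off_a:
            p00 += hinv[0, 0]
            p01 += hinv[0, 1]
            p11 += hinv[1, 1]
        elif j >= off_a:
            ja = j - off_a
            s_pr0 = 0.0
            s_pr1 = 0.0
            d_pr = 0.0
            for idx in range(ai_indptr[ja], ai_indptr[ja + 1]):
                k = ai_indices[idx]
                v = ai_data[idx]
                if k == ja:
                    d_pr = v
                else:
                    s_pr0 += v * theta[off_a + k, 0]
                    s_pr1 += v * theta[off_a + k, 1]
            rhs0 -= ginv[0, 0] * s_pr0 + ginv[0, 1] * s_pr1
            rhs1 -= ginv[1, 0] * s_pr0 + ginv[1, 1] * s_pr1
            p00 += d_pr * ginv[0, 0]
            p01 += d_pr * ginv[0, 1]
            p11 += d_pr * ginv[1, 1]
        # mean = P^{-1} rhs; sample via Cholesky of P: theta = mean + L'^{-1} z
        det = p00 * p11 - p01 * p01
        mu0 = (p11 * rhs0 - p01 * rhs1) / det
        mu1 = (p00 * rhs1 - p01 * rhs0) / det
        l00 = np.sqrt(p00)
        l10 = p01 / l00
        l11 = np.sqrt(p11 - l10 * l10)
        # solve L' x = z (back substitution) for N(0, P^{-1}) deviate
        x1 = z[j, 1] / l11
        x0 = (z[j, 0] - l10 * x1) / l00
        theta[j, 0] = mu0 + x0
        theta[j, 1] = mu1 + x1


@njit(cache=True)
def _bayesb_chain(xtx_diag, x, y, n_iter, burn_in, thin, pi_zero,
                  nu, s0, nu_e, se0, z_norm, z_chi_b, z_chi_sig, z_chi_e,
                  u_incl, beta_mean_out, mu_and_var_out, incl_mean_out):
    """BayesB single-site Gibbs with residual updating.

    x: (n, p) standardized covariates; spike-and-slab with P(beta_j = 0) =
    pi_zero and per-covariate slab variance sigma_j^2 ~ scaled-inv-chi2(nu, s0).
    Pre-generated deviates: z_norm (iters, p) normals for beta, z_chi_b
    (iters, p) chi2(nu + 1) for included sigma_j, z_chi_sig (iters, p)
    chi2(nu) for excluded sigma_j, z_chi_e (iters,) chi2(n) for sigma_e2,
    u_incl (iters, p) uniforms for the inclusion draw.
    """
    n, p = x.shape
    beta = np.zeros(p)
    sig = np.full(p, s0 * nu / (nu + 2.0))
    mu = np.mean(y)
    e = y - mu
    sigma_e2 = np.dot(e, e) / n + 1e-12
    log_prior_in = np.log(1.0 - pi_zero)
    log_prior_out = np.log(pi_zero)
    n_kept = 0
    for it in range(n_iter):
        # intercept
        old = mu
        mu = (np.sum(e) + n * old) / n + z_norm[it, p] * np.sqrt(sigma_e2 / n)
        e += old - mu
        for j in range(p):
            bj = beta[j]
            # restore partial residual r = e + x_j b_j implicitly via dots
            rx = np.dot(x[:, j], e) + xtx_diag[j] * bj
            cj = xtx_diag[j]
            # marginal log-likelihood ratio for inclusion given sigma_j
            v = cj + sigma_e2 / sig[j]
            log_in = log_prior_in + 0.5 * (rx * rx / (sigma_e2 * v)
                                           - np.log(v * sig[j] / sigma_e2))
            log_out = log_prior_out
            prob_in = 1.0 / (1.0 + np.exp(log_out - log_in))
            if u_incl[it, j] < prob_in:
                bnew = rx / v + z_norm[it, j] * np.sqrt(sigma_e2 / v)
                sig[j] = (nu * s0 + bnew * bnew) / z_chi_b[it, j]
            else:
                bnew = 0.0
                sig[j] = nu * s0 / z_chi_sig[it, j]
            if bnew != bj:
                diff = bj - bnew
                for i in range(n):
                    e[i] += x[i, j] * diff
                beta[j] = bnew
        sse = np.dot(e, e)
        sigma_e2 = (sse + nu_e * se0) / z_chi_e[it]
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_kept += 1
            for j in range(p):
                beta_mean_out[j] += beta[j]
                incl_mean_out[j] += 1.0 if beta[j] != 0.0 else 0.0
            mu_and_var_out[0] += mu
            mu_and_var_out[1] += sigma_e2
    for j in range(p):
        beta_mean_out[j] /= n_kept
        incl_mean_out[j] /= n_kept
    mu_and_var_out[0] /= n_kept
    mu_and_var_out[1] /= n_kept
    return n_kept
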