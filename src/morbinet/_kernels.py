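"""Numba kernels: single-site Gibbs sweeps for the pairwise binary model and
cyclic coordinate descent for l1-penalised GLM paths.

These are the hot loops; all orchestration, validation and scaling lives in
the public modules.  Family codes: 0 = gaussian, 1 = logistic, 2 = poisson.
"""

from __future__ import annotations

import numpy as np
from numba import njit

FAMILY_GAUSSIAN = 0
FAMILY_LOGISTIC = 1
FAMILY_POISSON = 2


@njit(cache=False)
def gibbs_chain(theta, tau, n, burn_in, thin, seed):
    """Single-chain Gibbs sampler for P(x) ∝ exp(tau·x + x'theta x / 2).

    Runs ``burn_in`` full sweeps, then records a state every ``thin`` sweeps
    until ``n`` draws are collected.  ``theta`` is symmetric with zero
    diagonal; states are in {0,1}^p.
    """
    np.random.seed(seed)
    p = tau.shape[0]
    x = np.empty(p, dtype=np.int8)
    for i in range(p):
        prob = 1.0 / (1.0 + np.exp(-tau[i]))
        x[i] = 1 if np.random.random() < prob else 0
    out = np.empty((n, p), dtype=np.int8)
    total_sweeps = burn_in + n * thin
    k = 0
    for sweep in range(total_sweeps):
        for i in range(p):
            eta = tau[i]
            for j in range(p):
                if j != i and x[j] == 1:
                    eta += theta[i, j]
            prob = 1.0 / (1.0 + np.exp(-eta))
            x[i] = 1 if np.random.random() < prob else 0
        if sweep >= burn_in and (sweep - burn_in + 1) % thin == 0:
            out[k] = x
            k += 1
            if k == n:
                break
    return out


@njit(cache=False)
def _soft(z, g):
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


@njit(cache=False)
def _cd_wls(Z, w, r, beta, lam, tol, max_iter):
    """Coordinate descent for (1/2n) Σ w_i (r_i + Z beta_old - Z beta)^2 + lam|beta|.

    ``r`` enters as the current residual (working response minus intercept
    minus Z beta) and is updated in place alongside ``beta``.  Intercept is
    handled by the caller via centred working responses.  Returns the number
    of sweeps used.
    """
    n, p = Z.shape
    denom = np.empty(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += w[i] * Z[i, j] * Z[i, j]
        denom[j] = acc / n
    for it in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if denom[j] <= 0.0:
                continue
            rho = 0.0
            for i in range(n):
                rho += w[i] * Z[i, j] * r[i]
            rho = rho / n + denom[j] * beta[j]
            new_b = _soft(rho, lam) / denom[j]
            diff = new_b - beta[j]
            if diff != 0.0:
                for i in range(n):
                    r[i] -= diff * Z[i, j]
                beta[j] = new_b
                ad = abs(diff)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            return it + 1
    return max_iter


@njit(cache=False)
def glm_cd_path(Z, y, family, lambdas, tol, max_inner, max_outer):
    """l1 GLM path by IRLS + cyclic coordinate descent with warm starts.

    ``Z`` must be column-standardised (mean 0, variance 1, population
    convention).  Returns ``(intercepts, betas)`` on the standardised scale,
    one row per lambda.  The intercept is unpenalised.
    """
    n, p = Z.shape
    k = lambdas.shape[0]
    betas = np.zeros((k, p))
    b0s = np.zeros(k)
    beta = np.zeros(p)

    ybar = y.mean()
    if family == FAMILY_GAUSSIAN:
        b0 = ybar
    elif family == FAMILY_LOGISTIC:
        mu0 = min(max(ybar, 1e-8), 1 - 1e-8)
        b0 = np.log(mu0 / (1.0 - mu0))
    else:
        b0 = np.log(max(ybar, 1e-8))

    w = np.ones(n)
    r = np.empty(n)
    eta = np.empty(n)

    for m in range(k):
        lam = lambdas[m]
        if family == FAMILY_GAUSSIAN:
            # residual given current beta, b0 = ybar always optimal (Z centred)
            b0 = ybar
            for i in range(n):
                acc = y[i] - b0
                for j in range(p):
                    if beta[j] != 0.0:
                        acc -= Z[i, j] * beta[j]
                r[i] = acc
            _cd_wls(Z, w, r, beta, lam, tol, max_inner)
        else:
            for outer in range(max_outer):
                # linear predictor and IRLS weights at the current iterate
                max_delta = 0.0
                wsum = 0.0
                wz = 0.0
                for i in range(n):
                    acc = b0
                    for j in range(p):
                        if beta[j] != 0.0:
                            acc += Z[i, j] * beta[j]
                    if acc > 30.0:
                        acc = 30.0
                    elif acc < -30.0:
                        acc = -30.0
                    eta[i] = acc
                for i in range(n):
                    if family == FAMILY_LOGISTIC:
                        mu = 1.0 / (1.0 + np.exp(-eta[i]))
                        wi = mu * (1.0 - mu)
                        if wi < 1e-6:
                            wi = 1e-6
                    else:
                        mu = np.exp(eta[i])
                        wi = mu
                        if wi < 1e-6:
                            wi = 1e-6
                    w[i] = wi
                    # working response z_i = eta + (y-mu)/w; store centred resid
                    r[i] = (y[i] - mu) / wi
                    wsum += wi
                    wz += wi * r[i]
                # intercept update on the working problem
                db0 = wz / wsum
                b0 += db0
                for i in range(n):
                    r[i] -= db0
                old_beta = beta.copy()
                _cd_wls(Z, w, r, beta, lam, tol, max_inner)
                for j in range(p):
                    d = abs(beta[j] - old_beta[j])
                    if d > max_delta:
                        max_delta = d
                if abs(db0) > max_delta:
                    max_delta = abs(db0)
                if max_delta < tol:
                    break
        b0s[m] = b0
        betas[m] = beta
    return b0s, betas
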