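"""Independent oracles used by the test suite.

Everything here is deliberately naive (dense linear algebra, plain loops)
and shares no code path with the package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def dense_conditional_from_joint(Sigma_u, A, c, nu2, y):
    """Conditional moments of u | y from the dense joint Gaussian.

    u ~ N(0, Sigma_u), y = c + A u + eps, eps ~ N(0, nu2 I).
    Returns (mean, cov) of u | y by textbook joint-normal conditioning.
    """
    Sigma_u = np.asarray(Sigma_u, float)
    A = np.asarray(A, float)
    S_uy = Sigma_u @ A.T
    S_yy = A @ Sigma_u @ A.T + nu2 * np.eye(A.shape[0])
    K = np.linalg.solve(S_yy, S_uy.T).T  # Sigma_uy Sigma_yy^{-1}
    mean = K @ (np.asarray(y, float) - np.asarray(c, float))
    cov = Sigma_u - K @ S_uy.T
    return mean, cov


def dense_block_conditional(P_post, b, u_full, block):
    """Conditional of one block of a joint Gaussian given the others.

    The joint density is prop to exp(-u'P u/2 + b'u).  ``block`` is an index
    array; the conditional of u[block] given u[~block] has precision
    P[block, block] and linear term b[block] - P[block, rest] u[rest].
    Returns (mean, cov).
    """
    P_post = np.asarray(P_post, float)
    n = P_post.shape[0]
    rest = np.setdiff1d(np.arange(n), block)
    Pbb = P_post[np.ix_(block, block)]
    lin = np.asarray(b, float)[block] - P_post[np.ix_(block, rest)] @ u_full[rest]
    cov = np.linalg.inv(Pbb)
    return cov @ lin, cov


def glm_exact_posterior(X, y, sigma2_beta, a, b, grid_size=4000):
    """Exact posterior means for the independent-error Gaussian GLM.

    Model: y = X beta + eps, eps ~ N(0, nu2 I), beta ~ N(0, sigma2_beta I),
    nu2 ~ IG(a, b).  The normal-inverse-gamma conjugacy gives beta | nu2 in
    closed form; the one-dimensional nu2 marginal
    p(nu2 | y) ∝ IG(nu2; a, b) N(y; 0, nu2 I + sigma2_beta X X')
    is integrated on a fine grid.  Returns (beta_mean, nu2_mean), exact up
    to quadrature error.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = y @ y

    # ballpark scale for the grid from the ridge residual variance
    K0 = XtX + np.eye(p) / sigma2_beta
    m0 = np.linalg.solve(K0, Xty)
    s0 = (b + 0.5 * (yty - m0 @ K0 @ m0)) / (a + n / 2.0)
    grid = np.exp(np.linspace(np.log(s0 / 8), np.log(s0 * 8), grid_size))

    logw = np.empty(grid_size)
    cond_beta = np.empty((grid_size, p))
    for i, nu2 in enumerate(grid):
        K = XtX + (nu2 / sigma2_beta) * np.eye(p)
        m = np.linalg.solve(K, Xty)
        # Woodbury: N(y; 0, nu2 I + s2b X X')
        sign, logdet_K = np.linalg.slogdet(K * sigma2_beta / nu2)
        assert sign > 0
        logdet = n * math.log(nu2) + logdet_K
        quad = (yty - Xty @ m) / nu2
        log_lik = -0.5 * (n * math.log(2 * math.pi) + logdet + quad)
        log_prior = a * math.log(b) - math.lgamma(a) - (a + 1) * math.log(nu2) - b / nu2
        logw[i] = log_lik + log_prior + math.log(nu2)  # log-grid Jacobian
        cond_beta[i] = m
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return w @ cond_beta, float(w @ grid)


def mvn_logpdf(u, cov):
    """Dense zero-mean multivariate normal log-density (plain formula)."""
    u = np.asarray(u, float)
    n = u.size
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    quad = u @ np.linalg.solve(cov, u)
    return -0.5 * (n * math.log(2 * math.pi) + logdet + quad)


# -- brute-force criteria recomputation (plain loops) -----------------------

def _logdens_matrix(y, mu_draws, nu2_draws):
    S, n = mu_draws.shape
    out = np.empty((S, n))
    for s in range(S):
        for i in range(n):
            out[s, i] = (
                -0.5 * math.log(2 * math.pi * nu2_draws[s])
                - 0.5 * (y[i] - mu_draws[s, i]) ** 2 / nu2_draws[s]
            )
    return out

def brute_dic(y, mu_draws, nu2_draws):
    ld = _logdens_matrix(y, mu_draws, nu2_draws)
    dev = np.array([-2.0 * ld[s].sum() for s in range(ld.shape[0])])
    dbar = dev.mean()
    mu_hat = mu_draws.mean(axis=0)
    nu2_hat = nu2_draws.mean()
    ll_hat = sum(
        -0.5 * math.log(2 * math.pi * nu2_hat)
        - 0.5 * (yi - mi) ** 2 / nu2_hat
        for yi, mi in zip(y, mu_hat)
    )
    dhat = -2.0 * ll_hat
    return dbar + (dbar - dhat)


def brute_waic(y, mu_draws, nu2_draws):
    ld = _logdens_matrix(y, mu_draws, nu2_draws)
    S, n = ld.shape
    lppd = 0.0
    p_w = 0.0
    for i in range(n):
        dens = np.exp(ld[:, i])
        lppd += math.log(dens.mean())
        p_w += ld[:, i].var(ddof=1)
    return -2.0 * (lppd - p_w)


def brute_lmpl(y, mu_draws, nu2_draws):
    ld = _logdens_matrix(y, mu_draws, nu2_draws)
    S, n = ld.shape
    total = 0.0
    for i in range(n):
        inv_dens = np.exp(-ld[:, i])
        cpo = 1.0 / inv_dens.mean()
        total += math.log(cpo)
    return total


def qmc_gaussian_crps(y, mu, sigma, n=1_000_000):
    """Sample-based CRPS estimate from n stratified Gaussian draws.

    Uses the energy form crps = E|X - y| - E|X - X'|/2 with X drawn as
    quantile midpoints (stratified sampling), and the exact sorted-sample
    U-statistic for the second term; integration error is O(1/n).
    """
    from scipy.special import ndtri

    u = (np.arange(n) + 0.5) / n
    x = mu + sigma * ndtri(u)  # already sorted
    t1 = np.mean(np.abs(x - y))
    i = np.arange(n)
    # U-statistic: sum_{i<j} (x_j - x_i) = sum_i (2i - n + 1) x_i for sorted x
    t2 = np.sum((2 * i - n + 1) * x) / (n * (n - 1))
    return t1 - t2
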