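"""Independent mini Gibbs samplers used as oracles for the reduction tests.

Each implements one classical Bayesian-lasso-family model directly (no shared
code with the package's sampler): coefficient priors conditioned on sigma^2,
fixed tuning parameter and fixed sigma^2, inverse-Gaussian latent updates via
scipy.  They are deliberately simple and slow.
"""

import numpy as np
from scipy.stats import invgauss


def _rig(rng, mean, shape):
    """Inverse-Gaussian draws through scipy's parameterization."""
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    return invgauss.rvs(mean / shape, scale=shape, size=mean.shape, random_state=rng)


def bayes_lasso(y, X, lam, sigma2, n_iter, burn, seed):
    """Standard Bayesian lasso: prior prop to exp(-lam |b_j| / sigma)."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    XtX, Xty = X.T @ X, X.T @ y
    sigma = np.sqrt(sigma2)
    inv_tau2 = np.ones(p)
    draws = []
    for it in range(n_iter):
        A = XtX + np.diag(inv_tau2)
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, Xty)
        beta = mean + sigma * np.linalg.solve(L.T, rng.standard_normal(p))
        inv_tau2 = _rig(rng, lam * sigma / np.maximum(np.abs(beta), 1e-10), lam**2)
        if it >= burn:
            draws.append(beta)
    return np.asarray(draws)


def bayes_fused_lasso(y, X, D, lam, sigma2, n_iter, burn, seed):
    """Bayesian fused lasso: prior prop to exp(-lam ||D b||_1 / sigma).

    Pure difference penalty; a tiny ridge (1e-8) keeps the prior precision
    invertible along the difference null space.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    XtX, Xty = X.T @ X, X.T @ y
    sigma = np.sqrt(sigma2)
    inv_omega2 = np.ones(D.shape[0])
    draws = []
    for it in range(n_iter):
        A = XtX + D.T @ (inv_omega2[:, None] * D) + 1e-8 * np.eye(p)
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, Xty)
        beta = mean + sigma * np.linalg.solve(L.T, rng.standard_normal(p))
        d = D @ beta
        inv_omega2 = _rig(rng, lam * sigma / np.maximum(np.abs(d), 1e-10), lam**2)
        if it >= burn:
            draws.append(beta)
    return np.asarray(draws)


def bayes_group_lasso(y, X, lam, sigma2, n_iter, burn, seed, sigma_inv=None):
    """Single-group Bayesian group lasso: prior prop to exp(-lam ||b||_S / sigma)
    with ||b||_S = sqrt(b' S^{-1} b)."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    S_inv = np.eye(p) if sigma_inv is None else sigma_inv
    XtX, Xty = X.T @ X, X.T @ y
    sigma = np.sqrt(sigma2)
    inv_taug2 = 1.0
    draws = []
    for it in range(n_iter):
        A = XtX + inv_taug2 * S_inv
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, Xty)
        beta = mean + sigma * np.linalg.solve(L.T, rng.standard_normal(p))
        norm = np.sqrt(max(beta @ S_inv @ beta, 1e-20))
        inv_taug2 = float(_rig(rng, lam * sigma / norm, lam**2)[0])
        if it >= burn:
            draws.append(beta)
    return np.asarray(draws)
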