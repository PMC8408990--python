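"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a different algorithm or a brute-force
route than the package implementation: an ADMM convex solver for the
sparse-group-lasso objective, full-dimensional Gaussian-density enumeration
for fine-mapping posteriors, and distribution-function evaluations from
scipy for the Cauchy combination. They are deliberately slow and simple.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats
from scipy.special import logsumexp


def sgl_objective(B, X_list, y_list, lam1, lam2):
    obj = 0.0
    for t, (X, y) in enumerate(zip(X_list, y_list)):
        r = y - X @ B[:, t]
        obj += r @ r / (2.0 * len(y))
    return (obj + lam1 * np.abs(B).sum()
            + lam2 * np.sqrt((B**2).sum(axis=1)).sum())


def admm_sparse_group_lasso(X_list, y_list, lam1, lam2, rho=1.0,
                            max_iter=50_000, tol=1e-13):
    """ADMM solver for min sum_t 1/(2N_t)||y_t - X_t b_t||^2 + penalties.

    Splitting B = C; the C-update applies entrywise soft-thresholding by
    lam1/rho followed by row-wise group shrinkage by lam2/rho, which is the
    exact proximal map of the sparse-group penalty. Returns the sparse
    iterate C, at which the objective is evaluated.
    """
    p = X_list[0].shape[1]
    T = len(X_list)
    grams = [X.T @ X / len(y) for X, y in zip(X_list, y_list)]
    covs = [X.T @ y / len(y) for X, y in zip(X_list, y_list)]
    solvers = [np.linalg.inv(G + rho * np.eye(p)) for G in grams]

    B = np.zeros((p, T))
    C = np.zeros((p, T))
    U = np.zeros((p, T))
    for _ in range(max_iter):
        for t in range(T):
            B[:, t] = solvers[t] @ (covs[t] + rho * (C[:, t] - U[:, t]))
        V = B + U
        C_new = np.sign(V) * np.maximum(np.abs(V) - lam1 / rho, 0.0)
        norms = np.sqrt((C_new**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(norms > 0, np.maximum(1 - (lam2 / rho) / norms, 0.0), 0.0)
        C_new = C_new * scale[:, None]
        primal = np.linalg.norm(B - C_new)
        dual = rho * np.linalg.norm(C_new - C)
        C = C_new
        U = U + B - C
        if primal < tol and dual < tol:
            break
    return C


def exhaustive_finemap_pips(z, omega, p0, v, ridge, max_causal=None):
    """PIPs by direct evaluation of full-dimensional Gaussian densities for
    every causal configuration (no Woodbury/low-rank identities)."""
    z = np.asarray(z, dtype=float)
    m = len(z)
    if max_causal is None:
        max_causal = m
    omega_r = np.atleast_2d(omega) + ridge * np.eye(m)
    log_null = stats.multivariate_normal.logpdf(z, mean=np.zeros(m), cov=omega_r)
    configs, logpost = [], []
    for k in range(0, max_causal + 1):
        for c in itertools.combinations(range(m), k):
            if k == 0:
                lp = log_null
            else:
                cols = omega_r[:, list(c)]
                cov = omega_r + v * cols @ cols.T
                lp = stats.multivariate_normal.logpdf(z, mean=np.zeros(m), cov=cov)
            logpost.append(lp + k * np.log(p0) + (m - k) * np.log1p(-p0))
            configs.append(c)
    logpost = np.array(logpost)
    post = np.exp(logpost - logsumexp(logpost))
    pips = np.zeros(m)
    for c, pr in zip(configs, post):
        for i in c:
            pips[i] += pr
    null_post = post[[i for i, c in enumerate(configs) if not c][0]]
    return pips, float(null_post)


def cauchy_combination_oracle(ps):
    """Combined P value via scipy's Cauchy distribution functions."""
    ps = np.asarray(ps, dtype=float)
    t_stat = float(np.mean(stats.cauchy.isf(ps)))
    return float(stats.cauchy.sf(t_stat))


def random_sgl_instance(rng, p_max=10, t_max=3, n=40):
    """A random small, well-conditioned sparse-group-lasso instance with
    standardized designs and centred responses."""
    p = int(rng.integers(2, p_max + 1))
    T = int(rng.integers(1, t_max + 1))
    X_list, y_list = [], []
    for _ in range(T):
        X = rng.standard_normal((n, p))
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        beta = rng.standard_normal(p) * (rng.random(p) < 0.5)
        y = X @ beta * 0.5 + rng.standard_normal(n)
        y_list.append(y - y.mean())
        X_list.append(X)
    lmax = max(np.max(np.abs(X.T @ y)) / n for X, y in zip(X_list, y_list))
    lam1 = float(rng.uniform(0.01, 0.8) * lmax)
    lam2 = float(rng.uniform(0.01, 0.8) * lmax)
    return X_list, y_list, lam1, lam2
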