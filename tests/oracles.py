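"""Independent reference implementations used as test oracles.

Everything here deliberately takes the slow, direct route (dense inverses,
double loops, closed forms) so it shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import linalg, stats


def naive_vanraden(genotypes, freqs):
    """Double-loop VanRaden G for tiny inputs."""
    X = np.asarray(genotypes, dtype=float)
    n, m = X.shape
    denom = 2.0 * sum(p * (1 - p) for p in freqs)
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for k in range(m):
                s += (X[i, k] - 2 * freqs[k]) * (X[j, k] - 2 * freqs[k])
            G[i, j] = s / denom
    return G


def naive_centered_scan(genotypes):
    X = np.asarray(genotypes, dtype=float)
    n, m = X.shape
    G = np.zeros((n, n))
    for k in range(m):
        x = X[:, k] - X[:, k].mean()
        G += np.outer(x, x)
    return G / m


def charpoly_eigenvalues(A):
    """Eigenvalues as the roots of the characteristic polynomial obtained by
    the Faddeev-LeVerrier recursion (no eigensolver involved)."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    coeffs = [1.0]
    M = np.zeros_like(A)
    for k in range(1, n + 1):
        M = A @ M + coeffs[-1] * np.eye(n)
        c = -np.trace(A @ M) / k
        coeffs.append(c)
    roots = np.roots(coeffs)
    return np.sort(roots.real)[::-1]


def dense_reml_loglik(delta, y, G, X):
    """REML log-likelihood at variance ratio delta = sigma_e2/sigma_u2 with
    sigma_u2 profiled out, computed with dense inverses and determinants."""
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    V0 = G + delta * np.eye(n)
    V0inv = linalg.inv(V0)
    xvx = X.T @ V0inv @ X
    beta = linalg.solve(xvx, X.T @ V0inv @ y)
    r = y - X @ beta
    s = float(r @ V0inv @ r)
    sigma_u2 = s / (n - p)
    _, logdet_v = np.linalg.slogdet(V0)
    _, logdet_xvx = np.linalg.slogdet(xvx)
    _, logdet_xx = np.linalg.slogdet(X.T @ X)
    return -0.5 * (
        (n - p) * math.log(2.0 * math.pi * sigma_u2)
        + (n - p)
        + logdet_v
        + logdet_xvx
        - logdet_xx
    )


def exact_gls_scan(y, genotypes, G, sigma_u2, sigma_e2):
    """Per-variant GLS with a full covariance solve; residual scale estimated
    per variant, Wald t with df = n - 2.  Returns (beta, se, p) arrays."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(genotypes, dtype=float)
    n, m = X.shape
    V = sigma_u2 * G + sigma_e2 * np.eye(n) if sigma_u2 > 0 else np.eye(n)
    L = linalg.cholesky(V, lower=True)
    yt = linalg.solve_triangular(L, y, lower=True)
    ct = linalg.solve_triangular(L, np.ones(n), lower=True)
    betas, ses, ps = np.empty(m), np.empty(m), np.empty(m)
    for j in range(m):
        xt = linalg.solve_triangular(L, X[:, j], lower=True)
        D = np.column_stack([ct, xt])
        dtd = D.T @ D
        if np.linalg.matrix_rank(dtd) < 2:
            betas[j], ses[j], ps[j] = 0.0, np.nan, 1.0
            continue
        sol = linalg.solve(dtd, D.T @ yt)
        r = yt - D @ sol
        sigma2 = float(r @ r) / (n - 2)
        cov = sigma2 * linalg.inv(dtd)
        betas[j] = sol[1]
        ses[j] = math.sqrt(max(cov[1, 1], 0.0))
        if ses[j] > 0:
            t = betas[j] / ses[j]
            ps[j] = 2.0 * stats.t.sf(abs(t), n - 2)
        else:
            ps[j] = 0.0 if betas[j] != 0 else 1.0
    ps = np.clip(ps, np.finfo(float).tiny, 1.0)
    return betas, ses, ps


def dense_H_from_identity(A, G, genotyped_last_k):
    """Literature joint-distribution H for a pedigree whose genotyped animals
    are the trailing block, built directly from A and G."""
    n = A.shape[0]
    k = genotyped_last_k
    u = slice(0, n - k)
    g = slice(n - k, n)
    A22 = A[g, g]
    A12 = A[u, g]
    A22inv = linalg.inv(A22)
    D = G - A22
    H = A.copy()
    H[u, u] = A[u, u] + A12 @ A22inv @ D @ A22inv @ A12.T
    H[u, g] = A12 + A12 @ A22inv @ D
    H[g, u] = H[u, g].T
    H[g, g] = G
    return H


def structured_grm(n, n_clusters, rng, m=400, rho=0.5):
    """PSD relationship matrix with family-block structure, from clustered
    pseudo-genotype rows."""
    cluster = rng.integers(0, n_clusters, size=n)
    base = rng.normal(size=(n_clusters, m))
    Z = math.sqrt(rho) * base[cluster] + math.sqrt(1 - rho) * rng.normal(size=(n, m))
    G = Z @ Z.T / m
    return G


def mvn_from_grm(G, sigma_u2, sigma_e2, rng):
    """Draw y = mu + u + e with u ~ N(0, sigma_u2 G)."""
    n = G.shape[0]
    w, U = np.linalg.eigh(G)
    w = np.clip(w, 0.0, None)
    u = U @ (np.sqrt(sigma_u2 * w) * rng.normal(size=n))
    e = rng.normal(0.0, math.sqrt(sigma_e2), size=n)
    return u + e
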