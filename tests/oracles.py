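"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive — exhaustive enumeration and dense
grid search with generic linear algebra — and shares no code path with the
package under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_min_wcss(X: np.ndarray, k: int) -> tuple[float, tuple[int, ...]]:
    """Minimum within-cluster sum of squares over all k-labelings.

    Enumerates every assignment of n points to k clusters (k^n of them),
    skipping assignments with empty clusters.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    best = np.inf
    best_assign: tuple[int, ...] = ()
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        labels = np.asarray(assign)
        wcss = 0.0
        for c in range(k):
            pts = X[labels == c]
            wcss += float(((pts - pts.mean(axis=0)) ** 2).sum())
        if wcss < best - 1e-15:
            best = wcss
            best_assign = assign
    return best, best_assign


def brute_force_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette from first principles: all pairwise distances.

    s(i) = (b - a) / max(a, b) with a the mean distance to own-cluster
    points (excluding self) and b the smallest mean distance to another
    cluster; singleton-cluster points score 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    scores = []
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            scores.append(0.0)
            continue
        a = dist[i, own & (np.arange(n) != i)].mean()
        b = min(
            dist[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def full_lmm_loglik(
    sigma_u: float,
    sigma_e: float,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Exact Gaussian log-likelihood with beta profiled by generic GLS.

    Builds the dense n x n marginal covariance sigma_e^2 I + sigma_u^2 ZZ'
    and inverts it directly — no block shortcuts.
    """
    n = len(y)
    Z = (groups[:, None] == np.unique(groups)[None, :]).astype(float)
    V = sigma_e**2 * np.eye(n) + sigma_u**2 * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(V)
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet + r @ Vinv @ r)
    return float(ll), beta


def grid_search_lmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_grid: int = 41,
    n_zoom: int = 5,
) -> dict:
    """Dense (sigma_u, sigma_e) grid maximizer of the exact log-likelihood.

    Iteratively zooms the grid around the running maximum so the final
    resolution is fine enough to compare parameters at 1e-4.
    """
    scale = float(np.std(y)) or 1.0
    u_lo, u_hi = 0.0, 3.0 * scale
    e_lo, e_hi = 1e-6 * scale, 3.0 * scale
    best = (-np.inf, 0.0, 0.0, None)
    for _ in range(n_zoom):
        us = np.linspace(u_lo, u_hi, n_grid)
        es = np.linspace(e_lo, e_hi, n_grid)
        for su in us:
            for se in es:
                ll, beta = full_lmm_loglik(su, se, X, y, groups)
                if ll > best[0]:
                    best = (ll, su, se, beta)
        du = (u_hi - u_lo) / (n_grid - 1)
        de = (e_hi - e_lo) / (n_grid - 1)
        u_lo, u_hi = max(best[1] - 2 * du, 0.0), best[1] + 2 * du
        e_lo, e_hi = max(best[2] - 2 * de, 1e-9 * scale), best[2] + 2 * de
    ll, su, se, beta = best
    return {"loglik": ll, "sigma_u": su, "sigma_e": se, "beta": beta}


def ols_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Textbook simple-regression slope and its standard error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    slope = ((x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    s2 = (resid**2).sum() / (n - 2)
    return slope, float(np.sqrt(s2 / sxx))
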