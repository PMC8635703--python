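"""Independent oracles used by the test suite.

Each is a deliberately simple, slow implementation kept free of the package
internals it checks (the polychoric grid oracle shares only the bivariate
normal CDF primitive, which has its own oracle test against scipy).
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy, ndtri

from resilnet._bvn import bvn_cdf


def nipals_pls1_residuals(X, Y, n_components=1, max_iter=1000, tol=1e-13):
    """Textbook NIPALS PLS2 loop; returns training residuals Y - Y_hat."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Xd, Yd = Xc.copy(), Yc.copy()
    Y_hat = np.zeros_like(Yc)
    for _ in range(n_components):
        u = Yd[:, 0].copy()
        for _ in range(max_iter):
            w = Xd.T @ u
            w /= np.linalg.norm(w)
            t = Xd @ w
            q = Yd.T @ t / (t @ t)
            u_new = Yd @ q / (q @ q)
            if np.linalg.norm(u_new - u) < tol * np.linalg.norm(u):
                u = u_new
                break
            u = u_new
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        q = Yd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, q)
        Y_hat = Y_hat + np.outer(t, q)
    return Y - (Y_hat + Y.mean(axis=0))


def polychoric_grid(table, step=1e-3):
    """Maximize the polychoric likelihood over a dense rho grid."""
    table = np.asarray(table, float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    n = table.sum()
    a = np.concatenate(([-np.inf], ndtri(np.cumsum(table.sum(1))[:-1] / n),
                        [np.inf]))
    b = np.concatenate(([-np.inf], ndtri(np.cumsum(table.sum(0))[:-1] / n),
                        [np.inf]))
    rhos = np.arange(-0.999, 0.999 + step / 2, step)
    best_ll, best_rho = -np.inf, 0.0
    for rho in rhos:
        C = bvn_cdf(a[:, None], b[None, :], rho)
        P = np.diff(np.diff(C, axis=0), axis=1)
        ll = float(xlogy(table, np.clip(P, 1e-320, None)).sum())
        if ll > best_ll:
            best_ll, best_rho = ll, float(rho)
    return best_rho


def _soft_offdiag(A, thr):
    out = np.sign(A) * np.maximum(np.abs(A) - thr, 0.0)
    np.fill_diagonal(out, np.diagonal(A))
    return out


def proximal_gradient_glasso(S, lam, tol=1e-12, max_iter=200000):
    """Proximal-gradient solver for the graphical lasso objective, run to
    tight tolerance; independent of the package's ADMM route."""
    S = np.asarray(S, float)
    k = S.shape[0]
    K = np.diag(1.0 / np.diagonal(S))
    step = 1.0 / np.linalg.eigvalsh(S).max() ** 2
    obj_prev = np.inf
    for _ in range(max_iter):
        G = S - np.linalg.inv(K)
        t = step
        while True:
            K_new = _soft_offdiag(K - t * G, t * lam)
            w = np.linalg.eigvalsh(K_new)
            if w.min() > 1e-12:
                break
            t /= 2.0
        K = K_new
        sign, logdet = np.linalg.slogdet(K)
        obj = -logdet + np.trace(S @ K) + lam * (
            np.abs(K).sum() - np.abs(np.diagonal(K)).sum()
        )
        if abs(obj_prev - obj) < tol * (1.0 + abs(obj)):
            break
        obj_prev = obj
    return K, float(obj)


def brute_force_apl(W):
    """Average shortest path length by exhaustive simple-path enumeration
    (feasible for <= 6 nodes). Returns (mean over finite unordered pairs,
    number of disconnected pairs)."""
    import itertools

    W = np.asarray(W, float)
    k = W.shape[0]
    dists = []
    n_disc = 0
    for i, j in itertools.combinations(range(k), 2):
        best = np.inf
        for m in range(k - 1):
            for mid in itertools.permutations(
                [v for v in range(k) if v not in (i, j)], m
            ):
                path = (i, *mid, j)
                d = 0.0
                ok = True
                for a, b in zip(path[:-1], path[1:]):
                    if W[a, b] == 0:
                        ok = False
                        break
                    d += 1.0 / abs(W[a, b])
                if ok:
                    best = min(best, d)
        if np.isfinite(best):
            dists.append(best)
        else:
            n_disc += 1
    if not dists:
        raise ValueError("fully disconnected")
    return float(np.mean(dists)), n_disc
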