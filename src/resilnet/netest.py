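"""Regularized partial-correlation network estimation for ordinal items.

The estimation chain mirrors standard psychometric-network practice:

1. pairwise polychoric correlations (two-step maximum likelihood: thresholds
   from the marginal category proportions, then the latent correlation by
   maximizing the bivariate-normal rectangle likelihood);
2. nearest-positive-definite repair of the pairwise matrix if needed;
3. graphical lasso over a descending penalty path, model selected by the
   Extended Bayesian Information Criterion (EBIC);
4. conversion of the selected precision matrix to partial correlations,
   optionally with the EBIC-consistent small-edge threshold applied.

Unregularized partial correlations (plain matrix inversion) are available as
a robustness variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import pinvh
from scipy.optimize import minimize_scalar
from scipy.special import ndtri, xlogy
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._bvn import bvn_cdf
from ._glasso import glasso, glasso_path, kkt_violation  # noqa: F401 (re-export)

__all__ = [
    "PolychoricMatrix",
    "NetworkModel",
    "polychoric_pair",
    "polychoric_matrix",
    "nearest_pd",
    "glasso",
    "ebic_glasso",
    "unregularized_pcor",
    "precision_to_pcor",
    "PolychoricCorrelation",
    "EBICGraphicalLasso",
]

RHO_BOUND = 0.999
_MIN_EIG = 1e-8


@dataclass
class PolychoricMatrix:
    """Pairwise polychoric correlation matrix with threshold estimates."""

    R: np.ndarray
    thresholds: list[np.ndarray]
    pd_repaired: bool
    n: int


@dataclass
class NetworkModel:
    """Partial-correlation network with its selection record."""

    weights: np.ndarray            # symmetric, zero diagonal
    precision: np.ndarray
    lambda_selected: float
    ebic: float
    gamma: float
    lambda_path: np.ndarray
    ebic_path: np.ndarray
    n: int
    settings: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        k = self.weights.shape[0]
        iu = np.triu_indices(k, 1)
        return int(np.count_nonzero(self.weights[iu]))

    def to_edge_list(self, names=None):
        """(node_i, node_j, weight) rows for the nonzero upper triangle."""
        k = self.weights.shape[0]
        if names is None:
            names = [f"V{i + 1:02d}" for i in range(k)]
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                if self.weights[i, j] != 0.0:
                    rows.append((names[i], names[j], float(self.weights[i, j])))
        return rows


def _thresholds_from_margin(counts: np.ndarray) -> np.ndarray:
    """Interior normal-quantile cut points from ordinal category counts."""
    n = counts.sum()
    cum = np.cumsum(counts)[:-1] / n
    return ndtri(cum)


def _pair_loglik(table, a_full, b_full, rho):
    C = bvn_cdf(a_full[:, None], b_full[None, :], rho)
    P = np.diff(np.diff(C, axis=0), axis=1)
    return float(xlogy(table, np.clip(P, 1e-320, None)).sum())


def polychoric_pair(table):
    """Two-step polychoric correlation from a two-way contingency table.

    Returns ``(rho, row_thresholds, col_thresholds)``. Empty margin
    categories are dropped; the latent correlation is the maximizer of the
    multinomial likelihood of the bivariate-normal rectangle probabilities,
    clamped to (-0.999, 0.999).
    """
    table = np.asarray(table, float)
    if table.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (table < 0).any():
        raise ValueError("table entries must be nonnegative counts")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            "polychoric correlation undefined: a margin has a single "
            "occupied category"
        )
    a = _thresholds_from_margin(table.sum(axis=1))
    b = _thresholds_from_margin(table.sum(axis=0))
    a_full = np.concatenate(([-np.inf], a, [np.inf]))
    b_full = np.concatenate(([-np.inf], b, [np.inf]))
    res = minimize_scalar(
        lambda r: -_pair_loglik(table, a_full, b_full, r),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x), a, b


def _crosstab(x, y, nx, ny):
    t = np.zeros((nx, ny))
    np.add.at(t, (x, y), 1.0)
    return t


def polychoric_matrix(items) -> PolychoricMatrix:
    """Pairwise polychoric correlation matrix of an ordinal item matrix.

    Items are recoded to consecutive category indices; thresholds are
    estimated once per item from its margin (valid with complete data) and
    shared across pairs. The matrix is repaired to positive definiteness by
    eigenvalue clipping when required, with the repair flagged.
    """
    items = np.asarray(items)
    if items.ndim != 2 or items.shape[1] < 2:
        raise ValueError("items must be an n x k matrix with k >= 2")
    n, k = items.shape
    if n < 20:
        warnings.warn(f"polychoric estimation with n={n} < 20 is unreliable")
    codes = np.empty_like(items, dtype=np.intp)
    n_cat = np.empty(k, dtype=int)
    thresholds = []
    for j in range(k):
        cats, codes[:, j] = np.unique(items[:, j], return_inverse=True)
        n_cat[j] = len(cats)
        if n_cat[j] < 2:
            raise ValueError(f"item {j} has a single observed category")
        counts = np.bincount(codes[:, j], minlength=n_cat[j]).astype(float)
        thresholds.append(_thresholds_from_margin(counts))
    R = np.eye(k)
    full = [np.concatenate(([-np.inf], t, [np.inf])) for t in thresholds]
    for i in range(k):
        for j in range(i + 1, k):
            t = _crosstab(codes[:, i], codes[:, j], n_cat[i], n_cat[j])
            res = minimize_scalar(
                lambda r: -_pair_loglik(t, full[i], full[j], r),
                bounds=(-RHO_BOUND, RHO_BOUND),
                method="bounded",
                options={"xatol": 1e-8},
            )
            R[i, j] = R[j, i] = float(res.x)
    repaired = False
    if np.linalg.eigvalsh(R).min() < _MIN_EIG:
        R = nearest_pd(R)
        repaired = True
    return PolychoricMatrix(R=R, thresholds=thresholds, pd_repaired=repaired, n=n)


def nearest_pd(R, min_eig: float = _MIN_EIG, max_iter: int = 200):
    """Nearest positive-definite correlation matrix by iterated eigenvalue
    clipping with unit-diagonal restoration. Identity on already-PD input."""
    R = np.asarray(R, float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    X = (R + R.T) / 2.0
    for _ in range(max_iter):
        w, Q = np.linalg.eigh(X)
        if w.min() >= min_eig and np.allclose(np.diagonal(X), 1.0, atol=1e-12):
            return X
        X = (Q * np.clip(w, min_eig, None)) @ Q.T
        d = np.sqrt(np.diagonal(X))
        X = X / np.outer(d, d)
        np.fill_diagonal(X, 1.0)
        X = (X + X.T) / 2.0
    if np.linalg.eigvalsh(X).min() < min_eig:  # pragma: no cover
        raise RuntimeError("positive-definite repair did not converge")
    return X


def _lambda_path(S, n_lambda, lambda_min_ratio):
    k = S.shape[-1]
    off = np.abs(S * ~np.eye(k, dtype=bool))
    lmax = np.maximum(off.reshape(*S.shape[:-2], -1).max(axis=-1), 1e-4)
    return np.exp(
        np.linspace(
            np.log(lmax), np.log(lmax * lambda_min_ratio), n_lambda, axis=-1
        )
    )


def _ebic_stats(Z, S, n, gamma):
    """EBIC of a stack of precision estimates against matrices S (batched)."""
    k = Z.shape[-1]
    iu = np.triu_indices(k, 1)
    E = np.count_nonzero(Z[..., iu[0], iu[1]], axis=-1)
    sign, logdet = np.linalg.slogdet(Z)
    tr = np.einsum("...ij,...ji->...", S, Z)
    loglik = n / 2.0 * (logdet - tr)
    ebic = -2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(k)
    return np.where(sign > 0, ebic, np.inf), E


def ebic_consistent_threshold(k: int, n: int) -> float:
    """Small-edge cut-off sqrt(log(k(k-1)/2) / n) used as robustness variant."""
    return float(np.sqrt(np.log(k * (k - 1) / 2.0) / n))


def precision_to_pcor(K):
    """Partial correlations -K_ij / sqrt(K_ii K_jj) with zero diagonal."""
    K = np.asarray(K, float)
    d = np.sqrt(np.diagonal(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def ebic_glasso(
    R,
    n: int,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    threshold: bool = True,
    tol: float = 1e-8,
) -> NetworkModel:
    """EBIC-selected graphical-lasso partial-correlation network.

    Parameters
    ----------
    R : correlation matrix (or PolychoricMatrix), assumed positive definite.
    n : number of subjects behind R (enters the Gaussian likelihood).
    gamma : EBIC hyperparameter; 0 reduces to ordinary BIC.
    threshold : if True, additionally zero selected partial correlations
        smaller in magnitude than sqrt(log(k(k-1)/2)/n).
    """
    if isinstance(R, PolychoricMatrix):
        R = R.R
    R = np.asarray(R, float)
    k = R.shape[0]
    if n <= k:
        warnings.warn(f"n={n} <= k={k}: EBIC selection is unreliable")
    lambdas = _lambda_path(R[None], n_lambda, lambda_min_ratio)
    best = None
    ebic_path = np.empty(n_lambda)
    n_nonempty = 0
    for j, Z, _failed in glasso_path(R[None], lambdas, tol_abs=tol, tol_rel=tol):
        ebic, E = _ebic_stats(Z, R[None], n, gamma)
        ebic_path[j] = ebic[0]
        n_nonempty += int(E[0] > 0)
        if best is None or ebic[0] < best[0]:
            best = (float(ebic[0]), float(lambdas[0, j]), Z[0].copy())
    if n_nonempty == 0:
        warnings.warn("every model on the penalty path is empty")
    ebic_val, lam_sel, K = best
    W = precision_to_pcor(K)
    if threshold:
        W[np.abs(W) < ebic_consistent_threshold(k, n)] = 0.0
    return NetworkModel(
        weights=W,
        precision=K,
        lambda_selected=lam_sel,
        ebic=ebic_val,
        gamma=gamma,
        lambda_path=lambdas[0],
        ebic_path=ebic_path,
        n=n,
        settings={
            "regularized": True,
            "thresholded": bool(threshold),
            "n_lambda": n_lambda,
            "lambda_min_ratio": lambda_min_ratio,
        },
    )


def ebic_glasso_batch(
    S,
    n: int,
    gamma: float = 0.5,
    n_lambda: int = 10,
    lambda_min_ratio: float = 0.01,
    threshold: bool = False,
    tol: float = 1e-5,
):
    """EBIC-glasso over a stack of correlation matrices (shared n).

    Returns ``(W, failed_mask)``: the (m, k, k) array of selected
    partial-correlation weights and a boolean mask of problems whose path
    did not fully converge. Used by the permutation network-comparison
    test, where thousands of re-estimations share the estimator settings.
    """
    S = np.asarray(S, float)
    m, k, _ = S.shape
    lambdas = _lambda_path(S, n_lambda, lambda_min_ratio)
    best_ebic = np.full(m, np.inf)
    best_K = np.empty_like(S)
    failed_mask = np.zeros(m, dtype=bool)
    for j, Z, failed in glasso_path(S, lambdas, tol_abs=tol, tol_rel=tol,
                                    strict=False):
        failed_mask[failed] = True
        ebic, _ = _ebic_stats(Z, S, n, gamma)
        better = ebic < best_ebic
        best_ebic[better] = ebic[better]
        best_K[better] = Z[better]
    d = np.sqrt(np.diagonal(best_K, axis1=1, axis2=2))
    W = -best_K / (d[:, :, None] * d[:, None, :])
    W[:, np.arange(k), np.arange(k)] = 0.0
    W = (W + np.swapaxes(W, 1, 2)) / 2.0
    if threshold:
        W[np.abs(W) < ebic_consistent_threshold(k, n)] = 0.0
    return W, failed_mask


def unregularized_pcor(R):
    """Partial correlations from plain inversion of a correlation matrix."""
    if isinstance(R, PolychoricMatrix):
        R = R.R
    R = np.asarray(R, float)
    w = np.linalg.eigvalsh(R)
    if w.min() <= 1e-12:
        raise np.linalg.LinAlgError("correlation matrix is singular")
    return precision_to_pcor(pinvh(R))


class PolychoricCorrelation(BaseEstimator):
    """Estimator wrapper around :func:`polychoric_matrix`.

    Fitted attributes: ``correlation_``, ``thresholds_``, ``pd_repaired_``,
    ``n_samples_``.
    """

    def fit(self, X, y=None):
        pm = polychoric_matrix(X)
        self.correlation_ = pm.R
        self.thresholds_ = pm.thresholds
        self.pd_repaired_ = pm.pd_repaired
        self.n_samples_ = pm.n
        return self


class EBICGraphicalLasso(BaseEstimator):
    """Partial-correlation network estimator for ordinal item matrices.

    Parameters
    ----------
    gamma : EBIC hyperparameter (default 0.5).
    n_lambda, lambda_min_ratio : penalty path layout.
    threshold : apply the EBIC-consistent small-edge cut-off to the
        selected network.
    corr_method : "polychoric" (latent-normal, for ordinal items) or
        "pearson" (treat item scores as Gaussian).
    regularize : if False, skip the lasso and return unregularized partial
        correlations (robustness variant).
    """

    def __init__(
        self,
        gamma: float = 0.5,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        threshold: bool = True,
        corr_method: str = "polychoric",
        regularize: bool = True,
    ):
        self.gamma = gamma
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.threshold = threshold
        self.corr_method = corr_method
        self.regularize = regularize

    def _correlation(self, X):
        if self.corr_method == "polychoric":
            pm = polychoric_matrix(X)
            R, repaired = pm.R, pm.pd_repaired
        elif self.corr_method == "pearson":
            R = np.corrcoef(np.asarray(X, float), rowvar=False)
            repaired = False
            if np.linalg.eigvalsh(R).min() < _MIN_EIG:
                R = nearest_pd(R)
                repaired = True
        else:
            raise ValueError(f"unknown corr_method {self.corr_method!r}")
        return R, repaired

    def fit(self, X, y=None):
        X = np.asarray(X)
        n = X.shape[0]
        R, repaired = self._correlation(X)
        self.correlation_ = R
        self.pd_repaired_ = repaired
        self.n_samples_ = n
        if self.regularize:
            net = ebic_glasso(
                R,
                n,
                gamma=self.gamma,
                n_lambda=self.n_lambda,
                lambda_min_ratio=self.lambda_min_ratio,
                threshold=self.threshold,
            )
        else:
            W = unregularized_pcor(R)
            net = NetworkModel(
                weights=W,
                precision=pinvh(R),
                lambda_selected=0.0,
                ebic=np.nan,
                gamma=self.gamma,
                lambda_path=np.array([]),
                ebic_path=np.array([]),
                n=n,
                settings={"regularized": False, "thresholded": False},
            )
        net.settings["corr_method"] = self.corr_method
        self.network_ = net
        self.weights_ = net.weights
        self.precision_ = net.precision
        self.lambda_ = net.lambda_selected
        self.ebic_ = net.ebic
        return self

    def get_network(self) -> NetworkModel:
        check_is_fitted(self, "network_")
        return self.network_
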