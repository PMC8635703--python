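"""Resilient-functioning scores from one-component PLSR residuals.

A single-component partial least squares regression predicts the four
processed mental-health outcomes from the stressor block. The per-subject
mean of the four prediction residuals is the resilient-functioning score:
positive means better mental health than the stress history predicts
(all outcomes are coded higher-is-healthier). The model's explained
variance is validated against permuted refits, and the sample is split at
score 0 into high (> 0) and low (<= 0) groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SIMPLSRegression",
    "PLSRFit",
    "PermutationResult",
    "ResilienceScoreSet",
    "fit_plsr",
    "permutation_test_plsr",
    "compute_resilience_scores",
    "split_groups",
    "ResilienceScorer",
]


@dataclass
class PLSRFit:
    """One fitted PLSR model: weights, scores, predictions, residuals."""

    n_components: int
    x_weights: np.ndarray     # p x A
    x_loadings: np.ndarray    # p x A
    y_loadings: np.ndarray    # q x A
    x_scores: np.ndarray      # n x A
    coefficients: np.ndarray  # p x q
    Y_hat: np.ndarray         # n x q
    E: np.ndarray             # n x q residuals, Y - Y_hat
    r2_total: float
    x_mean: np.ndarray
    y_mean: np.ndarray


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    n_perm: int
    p_value: float
    seed: object


@dataclass
class ResilienceScoreSet:
    score: np.ndarray
    group: np.ndarray         # "high" / "low"
    n_high: int
    n_low: int


class SIMPLSRegression(RegressorMixin, BaseEstimator):
    """Partial least squares regression, SIMPLS algorithm.

    The first weight vector maximizes the covariance between the X-score
    and the outcomes; further components repeat after projecting the
    cross-product matrix off the loadings found so far. For one component
    the predictions coincide with NIPALS PLSR.

    Parameters
    ----------
    n_components : number of latent components (the resilient-functioning
        model uses 1).
    algorithm : "simpls" (default) or "nipals" (classical alternating
        least squares with deflation; equivalent predictions).

    Attributes (after fit)
    ----------------------
    x_weights_, x_loadings_, y_loadings_ : per-component vectors.
    x_scores_ : training-sample component scores.
    coef_, intercept_ : regression form of the model.
    fitted_, residuals_ : training predictions and Y - Y_hat.
    r2_total_ : fraction of total (centered) outcome variance explained.
    """

    def __init__(self, n_components: int = 1, algorithm: str = "simpls"):
        self.n_components = n_components
        self.algorithm = algorithm

    def fit(self, X, Y):
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        q = Y.shape[1]
        A = self.n_components
        if not 1 <= A < n:
            raise ValueError("need n > n_components >= 1")
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("X and Y must be finite")
        x_mean = X.mean(axis=0)
        y_mean = Y.mean(axis=0)
        Xc = X - x_mean
        Yc = Y - y_mean
        if not (Xc.std(axis=0) > 0).any():
            raise ValueError("X block has zero variance")
        if self.algorithm == "simpls":
            R, T, P, Q = self._simpls(Xc, Yc, A)
        elif self.algorithm == "nipals":
            R, T, P, Q = self._nipals(Xc, Yc, A)
        else:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        coef = R @ Q.T
        self.x_weights_ = R
        self.x_scores_ = T
        self.x_loadings_ = P
        self.y_loadings_ = Q
        self.coef_ = coef
        self.intercept_ = y_mean - x_mean @ coef
        self.x_mean_, self.y_mean_ = x_mean, y_mean
        self.fitted_ = Xc @ coef + y_mean
        self.residuals_ = Y - self.fitted_
        sst = float((Yc**2).sum())
        sse = float(((Yc - Xc @ coef) ** 2).sum())
        self.r2_total_ = 1.0 - sse / sst
        self.n_features_in_ = p
        self.n_targets_ = q
        return self

    @staticmethod
    def _simpls(Xc, Yc, A):
        p, q = Xc.shape[1], Yc.shape[1]
        S = Xc.T @ Yc
        R = np.zeros((p, A))
        T = np.zeros((Xc.shape[0], A))
        P = np.zeros((p, A))
        Q = np.zeros((q, A))
        V = np.zeros((p, A))
        for a in range(A):
            U, s, Vt = np.linalg.svd(S, full_matrices=False)
            if s[0] <= max(Xc.shape) * np.finfo(float).eps * (abs(s[0]) + 1):
                raise ValueError(
                    f"rank of the deflated cross-product exhausted at "
                    f"component {a + 1}"
                )
            r = U[:, 0]
            t = Xc @ r
            norm_t = np.linalg.norm(t)
            if norm_t == 0:
                raise ValueError("degenerate X score")
            t /= norm_t
            r /= norm_t
            pv = Xc.T @ t
            qv = Yc.T @ t
            v = pv.copy()
            if a > 0:
                v -= V[:, :a] @ (V[:, :a].T @ pv)
            v /= np.linalg.norm(v)
            S = S - np.outer(v, v @ S)
            R[:, a], T[:, a], P[:, a], Q[:, a], V[:, a] = r, t, pv, qv, v
        return R, T, P, Q

    @staticmethod
    def _nipals(Xc, Yc, A, max_iter=500, tol=1e-12):
        p, q = Xc.shape[1], Yc.shape[1]
        Xd, Yd = Xc.copy(), Yc.copy()
        R_raw = np.zeros((p, A))   # weights w.r.t. deflated X
        T = np.zeros((Xc.shape[0], A))
        P = np.zeros((p, A))
        Q = np.zeros((q, A))
        for a in range(A):
            u = Yd[:, np.argmax(Yd.var(axis=0))].copy()
            w = np.zeros(p)
            for _ in range(max_iter):
                w_new = Xd.T @ u
                nw = np.linalg.norm(w_new)
                if nw == 0:
                    raise ValueError("degenerate NIPALS weight")
                w_new /= nw
                t = Xd @ w_new
                qv = Yd.T @ t / (t @ t)
                u_new = Yd @ qv / (qv @ qv)
                if np.linalg.norm(w_new - w) < tol:
                    w = w_new
                    break
                w, u = w_new, u_new
            t = Xd @ w
            pv = Xd.T @ t / (t @ t)
            qv = Yd.T @ t / (t @ t)
            Xd = Xd - np.outer(t, pv)
            Yd = Yd - np.outer(t, qv)
            nt = np.linalg.norm(t)
            R_raw[:, a], T[:, a], P[:, a], Q[:, a] = w, t / nt, pv, qv
        # convert deflated-X weights to direct weights: R = W (P'W)^-1
        Rmat = R_raw @ np.linalg.inv(P.T @ R_raw)
        # rescale so T = Xc R with unit-norm scores
        scale = 1.0 / np.linalg.norm(Xc @ Rmat, axis=0)
        return Rmat * scale, T, P / scale, Q / scale

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, float) @ self.coef_ + self.intercept_

    def score(self, X, Y):
        """Fraction of total outcome variance explained (pooled over
        outcome columns)."""
        Y = np.asarray(Y, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        E = Y - self.predict(X)
        sst = float(((Y - Y.mean(axis=0)) ** 2).sum())
        return 1.0 - float((E**2).sum()) / sst

    def to_fit(self) -> PLSRFit:
        check_is_fitted(self, "coef_")
        return PLSRFit(
            n_components=self.n_components,
            x_weights=self.x_weights_,
            x_loadings=self.x_loadings_,
            y_loadings=self.y_loadings_,
            x_scores=self.x_scores_,
            coefficients=self.coef_,
            Y_hat=self.fitted_,
            E=self.residuals_,
            r2_total=self.r2_total_,
            x_mean=self.x_mean_,
            y_mean=self.y_mean_,
        )


def fit_plsr(X, Y, n_components: int = 1, algorithm: str = "simpls") -> PLSRFit:
    """Fit the PLSR model and return its fit record."""
    return SIMPLSRegression(n_components, algorithm).fit(X, Y).to_fit()


def permutation_test_plsr(X, Y, n_perm: int = 1000, random_state=None,
                          n_components: int = 1) -> PermutationResult:
    """Permutation test of the PLSR explained variance.

    Rows of Y are permuted relative to X; the add-one estimator
    p = (1 + #{null >= observed}) / (1 + n_perm) keeps the p-value in (0, 1].
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    rng = np.random.default_rng(random_state)
    est = SIMPLSRegression(n_components)
    observed = est.fit(X, Y).r2_total_
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = est.fit(X, Y[rng.permutation(len(Y))]).r2_total_
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(
        observed_stat=float(observed), null_stats=null, n_perm=n_perm,
        p_value=float(p), seed=random_state,
    )


def compute_resilience_scores(fit: PLSRFit) -> ResilienceScoreSet:
    """Per-subject mean of the residual columns; positive = high group."""
    score = fit.E.mean(axis=1)
    group, n_high, n_low = split_groups(score)
    return ResilienceScoreSet(score=score, group=group,
                              n_high=n_high, n_low=n_low)


def split_groups(scores):
    """Split at 0: high iff score > 0, low iff score <= 0.

    Returns ``(labels, n_high, n_low)``; warns when a group is empty
    (network estimation downstream needs both groups populated).
    """
    scores = np.asarray(scores, float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    labels = np.where(scores > 0, "high", "low")
    n_high = int((scores > 0).sum())
    n_low = len(scores) - n_high
    if n_high == 0 or n_low == 0:
        warnings.warn("one of the resilient-functioning groups is empty")
    return labels, n_high, n_low


class ResilienceScorer(BaseEstimator):
    """Resilient-functioning scoring: one-component PLSR + residual means.

    ``fit(X, Y)`` fits the PLSR of outcomes Y (n x 4, higher = healthier)
    on stressors X, then exposes per-subject scores and the high/low split.

    Attributes
    ----------
    plsr_ : the fitted :class:`SIMPLSRegression`.
    score_ : per-subject resilient-functioning score (mean residual).
    group_ : "high" / "low" labels (high iff score > 0).
    n_high_, n_low_ : group sizes.
    r2_ : explained outcome variance of the PLSR.
    permutation_ : set by :meth:`permutation_test`.
    """

    def __init__(self, n_components: int = 1, algorithm: str = "simpls"):
        self.n_components = n_components
        self.algorithm = algorithm

    def fit(self, X, Y):
        self.plsr_ = SIMPLSRegression(self.n_components, self.algorithm).fit(X, Y)
        scores = compute_resilience_scores(self.plsr_.to_fit())
        self.score_ = scores.score
        self.group_ = scores.group
        self.n_high_ = scores.n_high
        self.n_low_ = scores.n_low
        self.r2_ = self.plsr_.r2_total_
        return self

    def permutation_test(self, X, Y, n_perm: int = 1000, random_state=None):
        check_is_fitted(self, "plsr_")
        self.permutation_ = permutation_test_plsr(
            X, Y, n_perm=n_perm, random_state=random_state,
            n_components=self.n_components,
        )
        return self.permutation_
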