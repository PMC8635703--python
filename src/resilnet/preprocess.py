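"""Raw item matrices -> PLSR design.

Outcomes: the WHO-5 sum score and the three inverted BSI-18 subscale sums
(all coded higher = healthier), each rank-inverse-normal transformed,
z-standardized, residualized on age and gender, and re-standardized.

Predictors: daily-hassle frequency and severity columns plus life-event
severity columns (58 + 58 + 27 = 143 by default), with any negative codes
(non-occurrence / declined) replaced by exactly 0 and otherwise left on
their raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .synthetic import BSI_SUBSCALE_MAP, CohortData

__all__ = [
    "MentalHealthScores",
    "PreprocessedDesign",
    "score_mental_health",
    "assemble_predictors",
    "standardize_and_residualize",
    "preprocess_design",
]


@dataclass
class MentalHealthScores:
    who5_sum: np.ndarray          # 0..25
    bsi_som_inv: np.ndarray       # inverted: 36 - raw subscale sum, 6..30
    bsi_dep_inv: np.ndarray
    bsi_anx_inv: np.ndarray

    COLUMNS = ("who5_sum", "bsi_som_inv", "bsi_dep_inv", "bsi_anx_inv")

    def as_matrix(self) -> np.ndarray:
        return np.column_stack(
            [self.who5_sum, self.bsi_som_inv, self.bsi_dep_inv, self.bsi_anx_inv]
        ).astype(float)


@dataclass
class PreprocessedDesign:
    Y: np.ndarray                 # n x 4, processed outcomes
    X: np.ndarray                 # n x p, stressor predictors
    y_names: tuple
    x_names: tuple
    residualization: dict         # removed age/gender coefficients per column


def _check_range(m, lo, hi, name):
    m = np.asarray(m)
    bad = (m < lo) | (m > hi)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"{name}[{i}, {j}] = {m[i, j]} outside [{lo}, {hi}]")
    return m


def score_mental_health(who5, bsi, subscale_map=None) -> MentalHealthScores:
    """Aggregate the mental-health items into four higher-is-healthier scores.

    Each BSI subscale sum (range 6..30) is inverted as (max + min) - raw =
    36 - raw, which preserves the printed scale.
    """
    who5 = _check_range(who5, 0, 5, "who5")
    bsi = _check_range(bsi, 1, 5, "bsi")
    if subscale_map is None:
        subscale_map = BSI_SUBSCALE_MAP
    idx = [np.asarray(v) for v in subscale_map.values()]
    flat = np.concatenate(idx)
    if len(flat) != bsi.shape[1] or len(np.unique(flat)) != bsi.shape[1]:
        raise ValueError("subscale map must partition the BSI items")
    sums = {k: bsi[:, np.asarray(v)].sum(axis=1) for k, v in subscale_map.items()}
    n_items = {k: len(v) for k, v in subscale_map.items()}
    inv = {k: (5 * n_items[k] + n_items[k]) - sums[k] for k in sums}
    return MentalHealthScores(
        who5_sum=who5.sum(axis=1),
        bsi_som_inv=inv["somatization"],
        bsi_dep_inv=inv["depression"],
        bsi_anx_inv=inv["anxiety"],
    )


def assemble_predictors(dh_freq, dh_sev, le_sev):
    """Concatenate the stressor blocks into the predictor matrix.

    Any value below 0 (codes for "did not occur" or "declined to answer")
    is set to exactly 0. Returns ``(X, column_names)``.
    """
    dh_freq, dh_sev, le_sev = (np.asarray(m, float) for m in (dh_freq, dh_sev, le_sev))
    n = dh_freq.shape[0]
    if dh_sev.shape[0] != n or le_sev.shape[0] != n:
        raise ValueError("stressor blocks must share the subject dimension")
    X = np.hstack([dh_freq, dh_sev, le_sev])
    X[X < 0] = 0.0
    names = (
        [f"DHf{i + 1:02d}" for i in range(dh_freq.shape[1])]
        + [f"DHs{i + 1:02d}" for i in range(dh_sev.shape[1])]
        + [f"LE{i + 1:02d}" for i in range(le_sev.shape[1])]
    )
    return X, tuple(names)


def rank_inverse_normal(x: np.ndarray) -> np.ndarray:
    """Van der Waerden transform: Phi^-1(rank / (n + 1)), average ranks on
    ties."""
    x = np.asarray(x, float)
    return ndtri(rankdata(x, method="average") / (len(x) + 1.0))


def standardize_and_residualize(Y, age, gender, normalize="rank-inverse-normal"):
    """Per outcome column: normalize, z-standardize, remove the OLS fit on
    intercept + age + gender, re-standardize.

    Returns ``(Y_processed, record)`` where the record stores the removed
    regression coefficients per column.
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects")
    age = np.asarray(age, float)
    gender = np.asarray(gender, float)
    if not np.isin(gender, [0.0, 1.0]).all():
        raise ValueError("gender must be coded as a binary 0/1 indicator")
    if normalize not in ("none", "rank-inverse-normal"):
        raise ValueError(f"unknown normalization {normalize!r}")
    C = np.column_stack([np.ones(n), age, gender])
    out = np.empty_like(Y)
    coefs = {}
    for j in range(Y.shape[1]):
        col = Y[:, j]
        if np.ptp(col) == 0:
            raise ValueError(f"outcome column {j} is constant")
        if normalize == "rank-inverse-normal":
            col = rank_inverse_normal(col)
        col = (col - col.mean()) / col.std()
        beta, *_ = np.linalg.lstsq(C, col, rcond=None)
        resid = col - C @ beta
        sd = resid.std()
        if sd == 0:
            raise ValueError(f"outcome column {j} fully explained by covariates")
        out[:, j] = resid / sd
        coefs[j] = beta.tolist()
    record = {"normalize": normalize, "coefficients": coefs,
              "covariates": ["intercept", "age", "gender"]}
    return out, record


def preprocess_design(cohort: CohortData, subscale_map=None,
                      normalize="rank-inverse-normal",
                      standardize_x=False) -> PreprocessedDesign:
    """Full pre-processing of a cohort into the PLSR design."""
    mh = score_mental_health(cohort.who5, cohort.bsi, subscale_map)
    Y, record = standardize_and_residualize(
        mh.as_matrix(), cohort.age, cohort.gender, normalize=normalize
    )
    X, x_names = assemble_predictors(cohort.dh_freq, cohort.dh_sev, cohort.le_sev)
    if standardize_x:
        sd = X.std(axis=0)
        keep = sd > 0
        X = X.copy()
        X[:, keep] = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        record["standardize_x"] = True
    else:
        record["standardize_x"] = False
    return PreprocessedDesign(
        Y=Y, X=X, y_names=MentalHealthScores.COLUMNS, x_names=x_names,
        residualization=record,
    )
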