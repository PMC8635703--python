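"""Synthetic cohort generator.

Emulates a cross-sectional undergraduate cohort assessed with two stressor
checklists (daily hassles: 58 items with 0-7 frequency and 1-5 severity;
life events: 27 items with 0-5 severity), two mental-health instruments
(WHO-5 well-being, 5 items 0-5; BSI-18 symptoms, 18 items 1-5 in three
6-item subscales) and the 10-item General Self-Efficacy scale (1-4), plus
age and gender.

Generating model
----------------
A latent stress factor drives all stressor items; latent mental health is
``stress_effect * stress + offset`` where the per-subject ``offset`` is the
ground-truth resilient functioning the downstream residual scoring should
recover. Subjects above the median offset form the "high" group and their
GSE items are thresholded draws from a latent Gaussian graphical model with
the high-connectivity precision matrix; the rest get the low-connectivity
matrix. All items are latent-normal variables discretized at fixed
cut-points, so polychoric estimation downstream is correctly specified.

All randomness flows from a single seed through one ordered
``SeedSequence.spawn`` split (demographics, latents, then one stream per
instrument).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

__all__ = [
    "SyntheticConfig",
    "CohortData",
    "GroundTruth",
    "ConfigError",
    "chain_precision",
    "sample_ordinal_from_ggm",
    "generate_cohort",
    "BSI_SUBSCALE_MAP",
    "DEFAULT_THRESHOLDS",
]

# Fixed item -> subscale partition of the 18 symptom items (6 each).
BSI_SUBSCALE_MAP: dict[str, tuple[int, ...]] = {
    "somatization": (0, 3, 6, 9, 12, 15),
    "depression": (1, 4, 7, 10, 13, 16),
    "anxiety": (2, 5, 8, 11, 14, 17),
}

# Standard-normal cut points per instrument, chosen so the marginal
# category frequencies land near the published sample descriptives
# (hassle frequency ~1.1/item, hassle severity ~1.05/item conditional on
# occurrence, life-event load ~0.74/item, well-being ~3.3/item, symptoms
# mostly absent, self-efficacy mean ~2.9/item).
DEFAULT_THRESHOLDS: dict[str, tuple[float, ...]] = {
    "dh_freq": tuple(ndtri([0.50, 0.72, 0.85, 0.92, 0.96, 0.98, 0.99])),
    "dh_sev": tuple(ndtri([0.35, 0.65, 0.85, 0.95])),
    "le_sev": tuple(ndtri([0.65, 0.7725, 0.8775, 0.9475, 0.9825])),
    "who5": tuple(ndtri([0.03, 0.10, 0.30, 0.60, 0.85])),
    "bsi": tuple(ndtri([0.60, 0.85, 0.95, 0.99])),
    "gse": (-1.6, -0.6, 0.6),
}

# Item loadings on the latent factors; mental-health loadings follow the
# instruments' published reliabilities (WHO-5 alpha ~ .92, BSI subscales
# alpha ~ .84), stressor loadings are moderate.
STRESSOR_LOADING = 0.4
WHO5_LOADING = 0.8
BSI_LOADING = 0.7


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration; names the violated invariant."""


def chain_precision(k: int = 10, pcor: float = 0.35) -> np.ndarray:
    """Unit-diagonal precision matrix of a chain graph whose adjacent-node
    partial correlations all equal ``pcor`` (positive definite for
    |pcor| < 0.5)."""
    K = np.eye(k)
    for i in range(k - 1):
        K[i, i + 1] = K[i + 1, i] = -pcor
    return K


def _check_spd(K, name):
    K = np.asarray(K, float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ConfigError(f"{name} must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ConfigError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(K).min() <= 0:
        raise ConfigError(f"{name} must be positive definite")
    return K


@dataclass
class SyntheticConfig:
    """Study conditions of the emulated cohort.

    Defaults reproduce the published sample descriptors: 875 subjects, 73%
    women, age 21.97 +/- 3.86 years, 58 hassle and 27 life-event items.
    """

    n_subjects: int = 875
    prop_female: float = 0.73
    age_mean: float = 21.97
    age_sd: float = 3.86
    n_dh: int = 58
    n_le: int = 27
    stress_effect: float = -0.5
    resilience_offset_sd: float = 1.0
    precision_high: np.ndarray = field(
        default_factory=lambda: chain_precision(10, 0.35)
    )
    precision_low: np.ndarray = field(
        default_factory=lambda: chain_precision(10, 0.15)
    )
    gse_mean_shift: float = 0.35
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if not 0.0 < self.prop_female < 1.0:
            raise ConfigError("prop_female must lie strictly in (0, 1)")
        if self.stress_effect > 0:
            raise ConfigError("stress_effect must be <= 0")
        if self.resilience_offset_sd < 0:
            raise ConfigError("resilience_offset_sd must be >= 0")
        if self.n_dh < 1 or self.n_le < 1:
            raise ConfigError("item counts must be positive")
        _check_spd(self.precision_high, "precision_high")
        _check_spd(self.precision_low, "precision_low")
        if self.precision_high.shape != self.precision_low.shape:
            raise ConfigError("group precision matrices must share a shape")
        for key, cuts in self.thresholds.items():
            c = np.asarray(cuts, float)
            if c.ndim != 1 or not np.all(np.diff(c) > 0):
                raise ConfigError(
                    f"thresholds[{key!r}] must be strictly increasing"
                )
        return self


@dataclass
class GroundTruth:
    """Latent quantities the generator used; enables recovery tests."""

    latent_stress: np.ndarray
    latent_health: np.ndarray
    resilience_offset: np.ndarray
    group_label_true: np.ndarray       # "high"/"low" per subject
    precision_high: np.ndarray
    precision_low: np.ndarray


@dataclass
class CohortData:
    """Subject-level item matrices for all five instruments plus covariates."""

    dh_freq: np.ndarray   # n x n_dh, 0..7
    dh_sev: np.ndarray    # n x n_dh, 0..5 (0 = did not occur)
    le_sev: np.ndarray    # n x n_le, 0..5 (0 = did not occur)
    who5: np.ndarray      # n x 5, 0..5
    bsi: np.ndarray       # n x 18, 1..5
    gse: np.ndarray       # n x 10, 1..4
    age: np.ndarray
    gender: np.ndarray    # 1 = female
    truth: GroundTruth | None = None

    @property
    def n_subjects(self) -> int:
        return self.dh_freq.shape[0]

    def validate(self) -> "CohortData":
        ranges = {
            "dh_freq": (self.dh_freq, 0, 7),
            "dh_sev": (self.dh_sev, 0, 5),
            "le_sev": (self.le_sev, 0, 5),
            "who5": (self.who5, 0, 5),
            "bsi": (self.bsi, 1, 5),
            "gse": (self.gse, 1, 4),
        }
        n = self.n_subjects
        for name, (m, lo, hi) in ranges.items():
            if m.shape[0] != n:
                raise ValueError(f"{name} has {m.shape[0]} rows, expected {n}")
            bad = (m < lo) | (m > hi)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"{name}[{i}, {j}] = {m[i, j]} outside [{lo}, {hi}]"
                )
        if len(self.age) != n or len(self.gender) != n:
            raise ValueError("covariate length mismatch")
        if not np.isin(self.gender, [0, 1]).all():
            raise ValueError("gender must be binary 0/1")
        off = (self.dh_freq == 0) & (self.dh_sev != 0)
        if off.any():
            i, j = np.argwhere(off)[0]
            raise ValueError(
                f"dh_sev[{i}, {j}] nonzero for a non-occurring hassle"
            )
        return self


def sample_ordinal_from_ggm(precision, thresholds, n, seed, mean=0.0):
    """Ordinal draws from a latent Gaussian graphical model.

    The latent covariance is the inverse of ``precision`` standardized to
    unit diagonal; each latent variable is shifted by ``mean`` and
    discretized at its (strictly increasing) cut points, yielding category
    codes 0..len(cuts).

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    K = np.asarray(precision, float)
    if np.linalg.eigvalsh(K).min() <= 0:
        raise ValueError("precision matrix must be positive definite")
    k = K.shape[0]
    cuts = [np.asarray(c, float) for c in _per_item_cuts(thresholds, k)]
    for c in cuts:
        if not np.all(np.diff(c) > 0):
            raise ValueError("thresholds must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = np.linalg.inv(K)
    d = np.sqrt(np.diagonal(cov))
    cov = cov / np.outer(d, d)
    z = rng.multivariate_normal(np.zeros(k), cov, size=int(n), method="cholesky")
    z = z + mean
    out = np.empty((int(n), k), dtype=np.int64)
    for j in range(k):
        out[:, j] = np.searchsorted(cuts[j], z[:, j], side="left")
    return out


def _per_item_cuts(thresholds, k):
    """Accept a single cut-point vector (shared) or one vector per item."""
    first = next(iter(thresholds), None)
    if first is None or np.ndim(first) == 0:
        return [np.asarray(thresholds, float)] * k
    cuts = [np.asarray(c, float) for c in thresholds]
    if len(cuts) != k:
        raise ValueError("need one cut-point vector per item")
    return cuts


def _loaded_items(rng, factor, loading, cuts, n_items, offset_cats=0):
    n = len(factor)
    noise = rng.normal(size=(n, n_items))
    latent = loading * factor[:, None] + np.sqrt(1.0 - loading**2) * noise
    return np.searchsorted(np.asarray(cuts, float), latent, side="left") + offset_cats


def generate_cohort(config: SyntheticConfig) -> CohortData:
    """Generate a complete cohort with ground truth. Deterministic in
    ``config.seed``; two calls with equal config are bit-identical."""
    config.validate()
    n = config.n_subjects
    streams = np.random.SeedSequence(config.seed).spawn(8)
    (rng_demo, rng_latent, rng_dhf, rng_dhs, rng_le,
     rng_who, rng_bsi, rng_gse) = map(np.random.default_rng, streams)

    age = rng_demo.normal(config.age_mean, config.age_sd, size=n)
    gender = (rng_demo.random(n) < config.prop_female).astype(np.int64)

    stress = rng_latent.normal(size=n)
    offset = rng_latent.normal(scale=config.resilience_offset_sd, size=n)
    health = config.stress_effect * stress + offset
    sd_h = np.sqrt(config.stress_effect**2 + config.resilience_offset_sd**2)
    health_std = health / sd_h if sd_h > 0 else np.zeros(n)

    thr = config.thresholds
    dh_freq = _loaded_items(rng_dhf, stress, STRESSOR_LOADING,
                            thr["dh_freq"], config.n_dh)
    dh_sev = _loaded_items(rng_dhs, stress, STRESSOR_LOADING,
                           thr["dh_sev"], config.n_dh, offset_cats=1)
    dh_sev = np.where(dh_freq == 0, 0, dh_sev)   # severity 0 iff no occurrence
    le_sev = _loaded_items(rng_le, stress, STRESSOR_LOADING,
                           thr["le_sev"], config.n_le)
    who5 = _loaded_items(rng_who, health_std, WHO5_LOADING, thr["who5"], 5)
    bsi = _loaded_items(rng_bsi, -health_std, BSI_LOADING, thr["bsi"], 18,
                        offset_cats=1)

    high = offset > np.median(offset)
    k = config.precision_high.shape[0]
    gse = np.empty((n, k), dtype=np.int64)
    gse[high] = sample_ordinal_from_ggm(
        config.precision_high, thr["gse"], int(high.sum()), rng_gse,
        mean=config.gse_mean_shift,
    ) + 1
    gse[~high] = sample_ordinal_from_ggm(
        config.precision_low, thr["gse"], int((~high).sum()), rng_gse,
    ) + 1

    truth = GroundTruth(
        latent_stress=stress,
        latent_health=health,
        resilience_offset=offset,
        group_label_true=np.where(high, "high", "low"),
        precision_high=np.asarray(config.precision_high, float),
        precision_low=np.asarray(config.precision_low, float),
    )
    return CohortData(
        dh_freq=dh_freq, dh_sev=dh_sev, le_sev=le_sev,
        who5=who5, bsi=bsi, gse=gse,
        age=age, gender=gender, truth=truth,
    ).validate()
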