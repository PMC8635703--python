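"""Descriptive two-group comparisons: t-tests with Cohen's d and item-wise
rank-sum tests with Bonferroni correction.

Signs follow the convention high-minus-low: positive d means the first
(high) group scores higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ComparisonRecord", "ttest_with_d", "wilcoxon_items", "bonferroni"]


@dataclass
class ComparisonRecord:
    name: str
    mean_high: float
    sd_high: float
    mean_low: float
    sd_low: float
    statistic: float
    p_raw: float
    p_corrected: float
    cohen_d: float | None
    test: str
    family_size: int
    flag: str = ""

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def bonferroni(p: float, family_size: int) -> float:
    """min(1, p * m)."""
    return float(min(1.0, p * family_size))


def cohen_d(x_high, x_low) -> float:
    """Pooled-SD standardized mean difference, high minus low."""
    x_high = np.asarray(x_high, float)
    x_low = np.asarray(x_low, float)
    n1, n2 = len(x_high), len(x_low)
    sp2 = ((n1 - 1) * x_high.var(ddof=1) + (n2 - 1) * x_low.var(ddof=1)) / (
        n1 + n2 - 2
    )
    if sp2 == 0:
        raise ValueError("zero pooled variance: Cohen's d undefined")
    return float((x_high.mean() - x_low.mean()) / np.sqrt(sp2))


def ttest_with_d(x_high, x_low, name: str = "", equal_var: bool = False,
                 family_size: int = 1) -> ComparisonRecord:
    """Two-sample t-test (Welch by default) with pooled-SD Cohen's d."""
    x_high = np.asarray(x_high, float)
    x_low = np.asarray(x_low, float)
    if len(x_high) < 2 or len(x_low) < 2:
        raise ValueError("both samples need n >= 2")
    d = cohen_d(x_high, x_low)
    res = stats.ttest_ind(x_high, x_low, equal_var=equal_var)
    return ComparisonRecord(
        name=name,
        mean_high=float(x_high.mean()), sd_high=float(x_high.std(ddof=1)),
        mean_low=float(x_low.mean()), sd_low=float(x_low.std(ddof=1)),
        statistic=float(res.statistic), p_raw=float(res.pvalue),
        p_corrected=bonferroni(float(res.pvalue), family_size),
        cohen_d=d,
        test="student-t" if equal_var else "welch-t",
        family_size=family_size,
    )


def wilcoxon_items(items_high, items_low, n_tests: int | None = None,
                   item_names=None) -> list[ComparisonRecord]:
    """Per-item two-sided Wilcoxon rank-sum tests, Bonferroni corrected.

    Uses the tie-corrected normal approximation. An item constant across
    both groups gets p = 1 with a flag instead of an error.
    """
    H = np.asarray(items_high, float)
    L = np.asarray(items_low, float)
    if H.ndim != 2 or L.ndim != 2 or H.shape[1] != L.shape[1]:
        raise ValueError("groups must share the item set")
    k = H.shape[1]
    m = n_tests if n_tests is not None else k
    if item_names is None:
        item_names = [f"item{j + 1:02d}" for j in range(k)]
    records = []
    for j in range(k):
        x, y = H[:, j], L[:, j]
        flag = ""
        if np.ptp(np.concatenate([x, y])) == 0:
            stat, p = np.nan, 1.0
            flag = "constant"
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
        records.append(ComparisonRecord(
            name=item_names[j],
            mean_high=float(x.mean()), sd_high=float(x.std(ddof=1)),
            mean_low=float(y.mean()), sd_low=float(y.std(ddof=1)),
            statistic=stat, p_raw=p,
            p_corrected=bonferroni(p, m),
            cohen_d=None,
            test="wilcoxon-rank-sum",
            family_size=m,
            flag=flag,
        ))
    return records
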