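"""Agreement and method-comparison statistics.

Implements the reliability layer used to compare volume-measurement methods
and observers: two-way intraclass correlation coefficients from variance
components, Bland-Altman analysis with a difference-on-mean regression for
proportional bias, paired method comparison, and Spearman rank correlation.

ICC models (single-measurement forms):

* ``two_way_random_absolute_single`` (ICC(2,1)) — raters are a random sample
  and systematic rater differences count as disagreement;
* ``two_way_mixed_consistency_single`` (ICC(3,1)) — raters are fixed and
  only subject-ordering consistency matters.

Both are computed from the two-way mean squares (subjects, raters, error)
of the complete subjects x raters grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "AgreementResult",
    "BlandAltmanResult",
    "icc",
    "bland_altman",
    "paired_compare",
    "spearman_rs",
]

ICCModel = Literal["two_way_random_absolute_single", "two_way_mixed_consistency_single"]


@dataclass(frozen=True)
class AgreementResult:
    icc: float
    model: ICCModel
    n_subjects: int
    n_raters: int


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    slope: float
    intercept: float
    r2: float
    p_slope: float


def icc(
    measurements: np.ndarray,
    model: ICCModel = "two_way_random_absolute_single",
) -> AgreementResult:
    """Intraclass correlation from a complete subjects x raters grid.

    Raises on missing cells (no imputation is attempted) and on grids with
    zero total variance, where reliability is undefined.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be a 2D subjects x raters grid")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("grid contains missing or non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0:
        raise ValueError("zero total variance: ICC undefined")
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    mse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum() / (
        (n - 1) * (k - 1)
    )

    if model == "two_way_random_absolute_single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif model == "two_way_mixed_consistency_single":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC model '{model}'")
    value = (msr - mse) / denom if denom != 0 else 1.0
    return AgreementResult(icc=float(value), model=model, n_subjects=n, n_raters=k)


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman limits of agreement with a difference-on-mean regression.

    Differences are ``x - y``; call with x = the method under evaluation and
    y = the reference so that size-dependent underestimation by x appears as
    a negative regression slope.  Limits of agreement are mean +/- 1.96 SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired measurements")
    d = x - y
    m = (x + y) / 2.0
    if np.allclose(m, m[0]):
        raise ValueError("pairwise means are constant: slope undefined")
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    fit = stats.linregress(m, d)
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue ** 2),
        p_slope=float(fit.pvalue),
    )


def paired_compare(
    x: np.ndarray, y: np.ndarray, test: Literal["t", "wilcoxon"] = "t"
) -> tuple[float, float]:
    """Mean paired difference x - y and its two-sided p-value.

    A paired t-test by default; Wilcoxon signed-rank as an alternative.
    Zero-variance differences are handled explicitly: p = 1 when the
    difference is identically zero, and the machine floor when a constant
    nonzero shift leaves nothing for the test statistic's denominator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be 1D, equal length, n >= 3")
    d = x - y
    mean_diff = float(d.mean())
    if np.allclose(d, d[0]):
        p = 1.0 if abs(mean_diff) < 1e-300 else float(np.finfo(float).tiny)
        return mean_diff, p
    if test == "t":
        p = float(stats.ttest_rel(x, y).pvalue)
    elif test == "wilcoxon":
        p = float(stats.wilcoxon(x, y).pvalue)
    else:
        raise ValueError(f"unknown test '{test}'")
    return mean_diff, p


def spearman_rs(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be 1D, equal length, n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)
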