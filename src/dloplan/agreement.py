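"""Method-agreement statistics for planning validation.

Implements, from the ANOVA decomposition up, the three tools of a classic
method-comparison design:

* ICC(2,1) — single-measure intraclass correlation, two-way random effects,
  absolute agreement, with the F-based 95 % confidence interval
  (McGraw & Wong A,1 form);
* Pearson correlation with the two-sided t-based p-value;
* Bland–Altman bias and limits of agreement (bias ± 1.96 SD of the paired
  differences, sample SD), with normal-theory confidence intervals.

Reliability bands: ICC above 0.90 excellent, above 0.75 reasonable, above
0.50 moderate, otherwise poor (boundary values fall in the lower band).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError

Z95 = 1.96  # multiplier defining the limits of agreement


@dataclass(frozen=True)
class RatingsTable:
    """Subjects x raters/methods measurement matrix (no missing cells)."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 2:
            raise DegenerateDataError(
                "ratings table needs >= 3 subjects and >= 2 raters")
        if not np.all(np.isfinite(arr)):
            raise DegenerateDataError("ratings table contains missing cells")
        object.__setattr__(self, "values", arr)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AgreementResult:
    """Bundle of agreement statistics for one measurement."""

    icc: float
    icc_ci95: tuple[float, float]
    pearson_r: float
    pearson_p: float
    ba_bias: float
    ba_loa: tuple[float, float]
    ba_bias_ci95: tuple[float, float]
    ba_loa_ci95: tuple[tuple[float, float], tuple[float, float]]
    label: str = ""


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of the two-way crossed layout."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_two_way_random_absolute(table: RatingsTable,
                                alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Returns (icc, (ci_lower, ci_upper)).  Raises
    :class:`DegenerateDataError` when the table carries no variance at all.
    """
    x = table.values
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300 or np.allclose(x, x.flat[0]):
        raise DegenerateDataError("zero total variance in ratings table")
    icc = (msr - mse) / denom

    # McGraw & Wong F-based interval
    if mse <= 0:
        return float(icc), (float(icc), float(icc))
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = ((n - 1) * k ** 2 * icc ** 2 * fj ** 2
          + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
    v = vn / vd if vd > 0 else 1.0
    f_upper = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lb = n * (msr - f_upper * mse) / (
        f_upper * (k * msc + (k * n - k - n) * mse) + n * msr)
    ub = n * (f_lower * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr)
    lb, ub = float(min(lb, ub)), float(max(lb, ub))
    return float(icc), (lb, ub)


def interpret_icc(icc: float) -> str:
    """Reliability band for an ICC value (boundaries go to the lower band)."""
    if not -1.0 <= icc <= 1.0:
        raise ValueError("icc must lie in [-1, 1]")
    if icc > 0.90:
        return "excellent"
    if icc > 0.75:
        return "reasonable"
    if icc > 0.50:
        return "moderate"
    return "poor"


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise DegenerateDataError("series must share a length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateDataError("a series has zero variance")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, float(p)


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

def bland_altman(x, y, alpha: float = 0.05):
    """Bias, limits of agreement and their confidence intervals.

    Differences are ``x - y``; the LoA are ``bias ± 1.96 * SD`` with the
    sample (n-1) standard deviation.  Returns the ba_* fields as a dict
    suitable for building an :class:`AgreementResult`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise DegenerateDataError("series must share a length >= 3")
    d = x - y
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - Z95 * sd, bias + Z95 * sd)
    t = sps.t.ppf(1 - alpha / 2, n - 1)
    se_bias = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(1.0 / n + Z95 ** 2 / (2.0 * (n - 1)))
    return {
        "ba_bias": bias,
        "ba_loa": loa,
        "ba_bias_ci95": (bias - t * se_bias, bias + t * se_bias),
        "ba_loa_ci95": (
            (loa[0] - t * se_loa, loa[0] + t * se_loa),
            (loa[1] - t * se_loa, loa[1] + t * se_loa),
        ),
    }


def compare_methods(x, y, label: str = "") -> AgreementResult:
    """Full two-method agreement panel (ICC, Pearson, Bland–Altman)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    table = RatingsTable(np.column_stack([x, y]), label=label)
    icc, ci = icc_two_way_random_absolute(table)
    r, p = pearson(x, y)
    ba = bland_altman(x, y)
    return AgreementResult(icc=icc, icc_ci95=ci, pearson_r=r, pearson_p=p,
                           label=label, **ba)


def agree_within(result: AgreementResult, max_allowed_difference: float) -> bool:
    """Bland–Altman verdict: do both limits of agreement stay inside the
    user's maximum allowed difference between methods?"""
    lo, hi = result.ba_loa
    return (abs(lo) <= max_allowed_difference
            and abs(hi) <= max_allowed_difference)
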