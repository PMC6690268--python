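"""Between-wrist agreement statistics.

Each 60 s epoch is one agreement target and the two wrist devices are the two
"raters": epochs are pooled across participants within a cohort slice.  The
module provides the partial Pearson correlation (controlling for participant),
the two-way mixed consistency intraclass correlation ICC(3,1)/(3,k) with an
F-based confidence interval, Bland-Altman limits of agreement oriented as
affected minus non-affected side, and qualitative category labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateVarianceError, DomainError, RangeError

# Default qualitative scales (configurable): half-open bins [lo, hi).
ICC_CATEGORIES = ((-1.0, "poor"), (0.5, "moderate"), (0.75, "good"), (0.9, "excellent"))
AUC_CATEGORIES = ((0.5, "low"), (0.7, "moderate"), (0.9, "high"))


@dataclass(frozen=True)
class BlandAltman:
    """Limits-of-agreement summary of paired differences a - b."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    proportional_bias_slope: float
    multiplier: float = 1.96


@dataclass(frozen=True)
class ICCResult:
    """Consistency intraclass correlation with an F-based interval."""

    icc: float
    ci_low: float
    ci_high: float
    form: str  # "(3,1)" or "(3,k)"
    level: float = 0.95


@dataclass(frozen=True)
class AgreementReport:
    """One cohort slice's agreement summary (one pair of table rows)."""

    n_epochs: int
    mean_a: float
    sd_a: float
    min_a: float
    max_a: float
    mean_b: float
    sd_b: float
    min_b: float
    max_b: float
    partial_r: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_category: str
    ba_mean_diff: float
    ba_sd_diff: float
    loa_low: float
    loa_high: float
    proportional_bias_slope: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def partial_pearson(x, y, group) -> float:
    """Pearson correlation of x and y after removing per-group means.

    Equivalent to partialling group-indicator variables out of both series;
    used to control for which participant contributed each epoch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    if not (x.shape == y.shape == group.shape) or x.ndim != 1:
        raise ValueError("x, y and group must be equal-length 1-d sequences")
    _, inv = np.unique(group, return_inverse=True)
    ngroups = inv.max() + 1
    counts = np.bincount(inv)
    xr = x - (np.bincount(inv, weights=x) / counts)[inv]
    yr = y - (np.bincount(inv, weights=y) / counts)[inv]
    ssx, ssy = np.dot(xr, xr), np.dot(yr, yr)
    if ssx <= 0 or ssy <= 0:
        raise DegenerateVarianceError("zero within-group variance")
    if x.size - ngroups < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    return float(np.dot(xr, yr) / np.sqrt(ssx * ssy))


def icc_consistency(ratings, form: str = "(3,k)", level: float = 0.95) -> ICCResult:
    """Two-way mixed, consistency-type ICC from the ANOVA mean squares.

    ``ratings`` is an (n_targets x k_raters) matrix with no missing cells.
    ICC(3,1) = (BMS - EMS) / (BMS + (k-1) EMS); ICC(3,k) = (BMS - EMS) / BMS,
    where BMS is the between-target and EMS the residual mean square.  The
    confidence interval follows the F-distribution construction of the
    two-way mixed model.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2:
        raise ValueError("ratings must be a 2-d matrix")
    n, k = r.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 targets and 2 raters")
    if np.isnan(r).any():
        raise ValueError("missing cells are not supported")
    if form not in ("(3,1)", "(3,k)"):
        raise ValueError("form must be '(3,1)' or '(3,k)'")
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((r - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if bms <= 0:
        raise DegenerateVarianceError("between-target mean square is zero")
    if form == "(3,1)":
        icc = (bms - ems) / (bms + (k - 1) * ems)
    else:
        icc = (bms - ems) / bms
    # F-based interval: F = BMS/EMS with (n-1, (n-1)(k-1)) df.
    alpha = 1 - level
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if ems == 0:
        return ICCResult(float(icc), float(icc), float(icc), form, level)
    f_obs = bms / ems
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    if form == "(3,1)":
        lo = (f_l - 1) / (f_l + (k - 1))
        hi = (f_u - 1) / (f_u + (k - 1))
    else:
        lo = 1 - 1 / f_l
        hi = 1 - 1 / f_u
    return ICCResult(float(icc), float(lo), float(hi), form, level)


def bland_altman(a, b, multiplier: float = 1.96) -> BlandAltman:
    """Limits of agreement for paired streams, differences oriented a - b.

    Returns the mean and sample (n-1) SD of the differences, limits
    ``mean ± multiplier * sd``, and the slope of d regressed on the pair mean
    (a + b)/2 as a proportional-bias diagnostic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-d sequences")
    if a.size < 2:
        raise DomainError("need at least 2 paired observations")
    d = a - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    means = (a + b) / 2.0
    var_m = np.var(means, ddof=1)
    slope = float(np.cov(means, d, ddof=1)[0, 1] / var_m) if var_m > 0 else 0.0
    return BlandAltman(
        n=a.size,
        mean_diff=mean_d,
        sd_diff=sd_d,
        loa_low=mean_d - multiplier * sd_d,
        loa_high=mean_d + multiplier * sd_d,
        proportional_bias_slope=slope,
        multiplier=multiplier,
    )


def categorize(value: float, table=ICC_CATEGORIES) -> str:
    """Label ``value`` by the half-open bin [breakpoint_i, breakpoint_{i+1})
    it falls in; the top bin is unbounded above at the scale's maximum of 1."""
    breaks = [b for b, _ in table]
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    if value < breaks[0] or value > 1.0:
        raise RangeError(f"value {value} outside the category table domain")
    label = table[0][1]
    for b, name in table:
        if value >= b:
            label = name
    return label


def agreement_report(
    cpm_affected,
    cpm_nonaffected,
    participant_ids,
    multiplier: float = 1.96,
    level: float = 0.95,
    icc_table=ICC_CATEGORIES,
) -> AgreementReport:
    """Assemble the full agreement summary for one cohort slice.

    All three sequences are epoch-aligned; epochs with a missing count on
    either wrist must be removed beforehand (see the pipeline, which filters
    to complete pairs).
    """
    a = np.asarray(cpm_affected, dtype=float)
    b = np.asarray(cpm_nonaffected, dtype=float)
    if a.size == 0:
        raise DomainError("empty slice")
    if np.isnan(a).any() or np.isnan(b).any():
        raise DomainError("agreement requires complete pairs on both wrists")
    try:
        r = partial_pearson(a, b, participant_ids)
    except DegenerateVarianceError:
        r = 1.0 if np.array_equal(a, b) else float("nan")
    icc = icc_consistency(np.column_stack([a, b]), form="(3,k)", level=level)
    ba = bland_altman(a, b, multiplier=multiplier)
    return AgreementReport(
        n_epochs=int(a.size),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        min_a=float(a.min()),
        max_a=float(a.max()),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        min_b=float(b.min()),
        max_b=float(b.max()),
        partial_r=float(r),
        icc=icc.icc,
        icc_ci_low=icc.ci_low,
        icc_ci_high=icc.ci_high,
        icc_category=categorize(min(icc.icc, 1.0), icc_table),
        ba_mean_diff=ba.mean_diff,
        ba_sd_diff=ba.sd_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        proportional_bias_slope=ba.proportional_bias_slope,
    )
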