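"""Interobserver-reliability statistics.

Agreement between observers measuring the same patients is summarised by:

* the single-rater intraclass correlation coefficient from a two-way
  random-effects model for absolute agreement, ICC(2,1), with its F-based
  95 % confidence interval (McGraw & Wong);
* the per-patient coefficient of variation (SD over observers / mean), and
  its unweighted mean over patients;
* Bland-Altman limits of agreement on paired measurements, with a
  Shapiro-Wilk normality check of the differences and an optional, explicit
  outlier-excluded recomputation.

The ICC interpretation bands applied to the CI endpoints are
poor (< 0.5), moderate (0.5-0.75), good (0.75-0.9) and excellent (> 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IccResult",
    "BlandAltmanResult",
    "icc_absolute_agreement",
    "interpret_icc",
    "cov_per_patient",
    "mean_cov",
    "bland_altman",
    "normality_test",
    "reliability_report",
    "format_report",
]

#: Relative tolerance below which the two-way ANOVA is treated as having no
#: variance at all (all cells equal): agreement is perfect by definition.
_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class IccResult:
    estimate: float
    ci_lo: float
    ci_hi: float
    n: int
    k: int
    degenerate: bool = False

    @property
    def interpretation(self) -> str:
        return interpret_icc(self)


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_lo: float
    loa_hi: float
    normality_p: float
    n: int
    excluded: tuple = ()
    # Recomputed limits after exclusion, if an exclusion list was given.
    mean_diff_excl: float | None = None
    sd_diff_excl: float | None = None
    loa_lo_excl: float | None = None
    loa_hi_excl: float | None = None


# ---------------------------------------------------------------------------
# ICC


def _two_way_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Mean squares of the two-way ANOVA without replication.

    Rows are subjects (patients), columns are raters (observers).
    Returns (MSR, MSC, MSE) — rows, columns, residual.
    """
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_absolute_agreement(data, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``data`` is an n x k matrix (n >= 2 subjects as rows, k >= 2 raters as
    columns, no missing cells).  The point estimate is

        (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    and the confidence interval uses the F-distribution method for this ICC
    form.  If the data have no variance at all (every cell equal), agreement
    is perfect by definition: the result is 1.0 with a degenerate flag.
    """
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("ICC input must be a 2D (subjects x raters) matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 subjects and k >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("ICC input contains missing or non-finite cells")

    msr, msc, mse = _two_way_mean_squares(x)
    scale = max(abs(x).max(), 1.0) ** 2
    if max(msr, msc, mse) <= _DEGENERATE_RTOL * scale:
        return IccResult(1.0, 1.0, 1.0, n, k, degenerate=True)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    est = (msr - mse) / denom

    if mse <= _DEGENERATE_RTOL * scale and msc <= _DEGENERATE_RTOL * scale:
        # Identical raters on varying subjects: perfect absolute agreement;
        # the F-based CI is undefined (division by 1 - r).
        return IccResult(1.0, 1.0, 1.0, n, k, degenerate=True)

    # F-based CI (McGraw & Wong case two-way random, absolute agreement).
    r = est
    a = k * r / (n * (1.0 - r))
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)

    est_clip = float(np.clip(est, -1.0, 1.0))
    lo = float(min(np.clip(lo, -1.0, 1.0), est_clip))
    hi = float(max(np.clip(hi, -1.0, 1.0), est_clip))
    return IccResult(est_clip, lo, hi, n, k)


def _band(x: float) -> str:
    if x < 0.5:
        return "poor"
    if x <= 0.75:
        return "moderate"
    if x <= 0.9:
        return "good"
    return "excellent"


def interpret_icc(result: IccResult) -> str:
    """Interpretation band(s) of the 95 % CI.

    When both CI endpoints fall in the same band that band is returned;
    otherwise a range such as ``"good to excellent"``.
    """
    lo_band, hi_band = _band(result.ci_lo), _band(result.ci_hi)
    if lo_band == hi_band:
        return lo_band
    return f"{lo_band} to {hi_band}"


# ---------------------------------------------------------------------------
# Coefficient of variation


def cov_per_patient(values, ddof: int = 1) -> float:
    """CoV of one patient's observer measurements, as a percentage.

    Sample SD (ddof=1) over the k observer values divided by their mean.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("CoV requires at least two observer values")
    m = v.mean()
    if m <= 0:
        raise ValueError(f"CoV undefined for non-positive mean ({m})")
    return float(v.std(ddof=ddof) / m * 100.0)


def mean_cov(matrix, ddof: int = 1) -> float:
    """Unweighted mean over patients of the per-patient CoV (percent).

    ``matrix`` is n patients x k observers.
    """
    x = np.asarray(matrix, dtype=np.float64)
    return float(np.mean([cov_per_patient(row, ddof) for row in x]))


# ---------------------------------------------------------------------------
# Bland-Altman


def bland_altman(pairs, exclude: list | None = None) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements.

    ``pairs`` is a sequence of (x, y); differences are d = x - y.  Limits of
    agreement are mean(d) +/- 1.96 * SD(d) (sample SD).  Normality of the
    differences is checked with the Shapiro-Wilk test.  ``exclude`` is an
    explicit list of 0-based pair indices (e.g. visually identified
    outliers); when given, the limits are *also* recomputed without those
    pairs and reported alongside the originals.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (x, y)")
    if arr.shape[0] < 3:
        raise ValueError("Bland-Altman requires at least 3 pairs")
    d = arr[:, 0] - arr[:, 1]

    def _limits(dd):
        m = float(dd.mean())
        s = float(dd.std(ddof=1))
        return m, s, m - 1.96 * s, m + 1.96 * s

    m, s, lo, hi = _limits(d)
    try:
        p = normality_test(d)
    except ValueError:
        p = float("nan")  # degenerate (constant differences)

    kw: dict = {}
    excluded: tuple = ()
    if exclude:
        excluded = tuple(exclude)
        keep = np.ones(len(d), dtype=bool)
        keep[list(excluded)] = False
        if keep.sum() < 3:
            raise ValueError("fewer than 3 pairs remain after exclusion")
        me, se, loe, hie = _limits(d[keep])
        kw = dict(
            mean_diff_excl=me, sd_diff_excl=se, loa_lo_excl=loe, loa_hi_excl=hie
        )
    return BlandAltmanResult(m, s, lo, hi, p, n=len(d), excluded=excluded, **kw)


def normality_test(values) -> float:
    """Shapiro-Wilk p-value; p < 0.05 indicates a non-normal distribution."""
    v = np.asarray(values, dtype=np.float64)
    if not 3 <= v.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("normality test degenerate: all values identical")
    return float(stats.shapiro(v).pvalue)


# ---------------------------------------------------------------------------
# Study-level report


def _pivot(table: pd.DataFrame, workflow: str, method: str, outcome: str):
    sub = table[(table["workflow"] == workflow) & (table["method"] == method)]
    pivot = sub.pivot_table(
        index="patient", columns="observer", values=outcome, aggfunc="first"
    )
    return pivot


def reliability_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per (workflow, method) reliability summary over a long-format table.

    ``table`` has columns patient, observer, workflow, method, MTV, TLG.
    For each (workflow, method) and each outcome the report carries the mean
    and range of the per-patient observer means, the mean and range of the
    per-patient CoV, and the ICC with its 95 % CI and interpretation —
    mirroring the usual interobserver-reliability table layout.  Rows with
    incomplete patient x observer cells are flagged and their ICC left NaN.
    """
    required = {"patient", "observer", "workflow", "method", "MTV", "TLG"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    rows = []
    combos = table[["workflow", "method"]].drop_duplicates().itertuples(index=False)
    for workflow, method in combos:
        row: dict = {"workflow": workflow, "method": method, "complete": True}
        for outcome in ("MTV", "TLG"):
            pivot = _pivot(table, workflow, method, outcome)
            x = pivot.to_numpy(dtype=np.float64)
            pre = outcome.lower()
            if x.size == 0 or np.isnan(x).any():
                row["complete"] = False
                for col in ("mean", "min", "max", "mean_cov", "cov_min", "cov_max",
                            "icc", "icc_lo", "icc_hi"):
                    row[f"{pre}_{col}"] = np.nan
                row[f"{pre}_interpretation"] = "incomplete"
                continue
            patient_means = x.mean(axis=1)
            # A patient on whom every observer measured exactly 0 is perfect
            # agreement (CoV 0); a zero mean with disagreement is undefined.
            covs = np.array(
                [
                    0.0 if r.mean() == 0 and r.std() == 0 else cov_per_patient(r)
                    for r in x
                ]
            )
            icc = icc_absolute_agreement(x)
            row.update(
                {
                    f"{pre}_mean": float(patient_means.mean()),
                    f"{pre}_min": float(patient_means.min()),
                    f"{pre}_max": float(patient_means.max()),
                    f"{pre}_mean_cov": float(covs.mean()),
                    f"{pre}_cov_min": float(covs.min()),
                    f"{pre}_cov_max": float(covs.max()),
                    f"{pre}_icc": icc.estimate,
                    f"{pre}_icc_lo": icc.ci_lo,
                    f"{pre}_icc_hi": icc.ci_hi,
                    f"{pre}_interpretation": icc.interpretation,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Printable version of :func:`reliability_report`.

    Volumes/TLG to whole numbers, CoV to 2 decimals (percent), ICC to
    2 decimals with the 95 % CI in parentheses.
    """
    out = []
    for _, r in report.iterrows():
        row = {"workflow": r["workflow"], "method": r["method"]}
        for pre, label in (("mtv", "MTV"), ("tlg", "TLG")):
            if not r["complete"] or np.isnan(r[f"{pre}_icc"]):
                row[f"{label} mean(range)"] = "incomplete"
                row[f"{label} CoV%(range)"] = ""
                row[f"{label} ICC(95%CI)"] = ""
                continue
            row[f"{label} mean(range)"] = (
                f"{r[f'{pre}_mean']:.0f}({r[f'{pre}_min']:.0f}-{r[f'{pre}_max']:.0f})"
            )
            row[f"{label} CoV%(range)"] = (
                f"{r[f'{pre}_mean_cov']:.2f}"
                f"({r[f'{pre}_cov_min']:.2f}-{r[f'{pre}_cov_max']:.2f})"
            )
            row[f"{label} ICC(95%CI)"] = (
                f"{r[f'{pre}_icc']:.2f}"
                f"({r[f'{pre}_icc_lo']:.2f}-{r[f'{pre}_icc_hi']:.2f})"
            )
        out.append(row)
    return pd.DataFrame(out)
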