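"""The eight binary seasonality classification methods.

Each method maps a monthly proportion series and a significance level to a
:class:`TestResult` with a seasonal/non-seasonal verdict.  The methods:

======  =============================================================
ED      Edwards harmonic test: Poisson GLM on sine/cosine of calendar
        month, likelihood-ratio against an intercept-only model.  Runs
        on the raw series (the harmonic basis absorbs no trend, and the
        test is periodic, so trend removal is not required).
FR      Friedman rank test on the year-by-month matrix of detrended
        values (within-year ranking of the 12 months).
AR      Likelihood-ratio test of a seasonal ARIMA augmentation against
        the stepwise-selected non-seasonal ARIMA of the detrended
        series.
QS      Positive-part autocorrelations of the detrended series at lags
        12 and 24, Ljung-Box-weighted, referred to chi-square(2).
ET      Likelihood-ratio test of the best additive-seasonal
        exponential-smoothing state-space model against the best
        non-seasonal one, on the detrended series.
KW      Kruskal-Wallis rank test across the 12 calendar-month groups of
        detrended values.
WE      Welch heteroscedastic one-way ANOVA across month groups of
        detrended values.
AA      Stepwise (Hyndman-Khandakar) auto-ARIMA selection on the
        detrended series; seasonal iff the selected model has a
        seasonal component.  Alpha-free.
======  =============================================================

The seasonal verdict for p-valued methods is the strict rule p < alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import ClassVar, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import (
    DegenerateSeriesError,
    DetrendedSeries,
    detrend_difference,
    detrend_linear,
    fold_year_month,
    sample_autocorrelation,
)
from .series import ProportionSeries

__all__ = [
    "METHODS",
    "DEFAULT_ALPHAS",
    "TestResult",
    "TestConfig",
    "FitFailureError",
    "edwards_test",
    "friedman_test",
    "kruskal_wallis_test",
    "welch_test",
    "qs_test",
    "ets_lrt_test",
    "arima_lrt_test",
    "auto_arima_test",
    "classify_all",
    "results_to_frame",
]

#: fixed method order used throughout (columns of classification matrices)
METHODS = ("ED", "FR", "AR", "QS", "ET", "KW", "WE", "AA")

DEFAULT_ALPHAS = (0.01, 0.05, 0.1)


class FitFailureError(RuntimeError):
    """Model estimation failed for a series."""


@dataclass(frozen=True)
class TestResult:
    """One method's verdict on one series at one significance level.

    ``p_value`` is absent (None) for AA, which has no hypothesis-test
    construction; ``seasonal`` is None when the method failed on the
    series, with ``error`` naming the failure.
    """

    __test__: ClassVar[bool] = False  # not a pytest class despite the name

    series_id: str
    method: str
    alpha: float
    seasonal: bool | None
    statistic: float | None = None
    df: float | None = None
    p_value: float | None = None
    detail: dict = field(default_factory=dict)
    error: str | None = None

    def __post_init__(self):
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.p_value is not None and self.seasonal is not None:
            assert self.seasonal == (self.p_value < self.alpha)


@dataclass(frozen=True)
class TestConfig:
    """Options shared across the battery.

    detrend: 'ols' (regression residuals, default) or 'diff' (first
    differences).  Differencing breaks calendar-year alignment, so the
    rank/ANOVA methods (FR, KW, WE) always use OLS residuals regardless.
    ed_scale: multiplier turning per-thousand proportions into Poisson
    pseudo-counts for ED (default 1000; with a one-million-person
    denominator this reproduces the true event counts).
    ets_damped: include damped-trend candidates in both ET arms.
    max_p/max_q/max_P/max_Q: stepwise search bounds for AR and AA.
    """

    __test__: ClassVar[bool] = False  # not a pytest class despite the name

    detrend: str = "ols"
    ed_scale: float = 1000.0
    ets_damped: bool = False
    max_p: int = 3
    max_q: int = 3
    max_P: int = 1
    max_Q: int = 1

    def detrend_series(self, series, rank_safe: bool = False) -> DetrendedSeries:
        if self.detrend == "ols" or rank_safe:
            return detrend_linear(series)
        if self.detrend == "diff":
            return detrend_difference(series)
        raise ValueError(f"unknown detrend mode {self.detrend!r}")


DEFAULT_CONFIG = TestConfig()


def _result(series, method, alpha, stat, df, p, detail=None):
    return TestResult(
        series_id=series.series_id,
        method=method,
        alpha=alpha,
        seasonal=bool(p < alpha),
        statistic=float(stat),
        df=df,
        p_value=float(p),
        detail=detail or {},
    )


# ---------------------------------------------------------------------------
# ED: Edwards harmonic Poisson regression
# ---------------------------------------------------------------------------

def edwards_test(
    series: ProportionSeries, alpha: float, config: TestConfig = DEFAULT_CONFIG
) -> TestResult:
    """Harmonic Poisson-GLM likelihood-ratio test on the raw series.

    Pseudo-counts y_t = round(scale * value_t) are regressed (log link) on
    cos and sin of the calendar-month angle; the deviance drop against the
    intercept-only model is referred to chi-square with 2 df.  The fitted
    harmonic's amplitude and peak month are recorded in ``detail``.
    """
    import statsmodels.api as sm

    y = np.round(config.ed_scale * series.values)
    if not np.any(y > 0):
        raise DegenerateSeriesError(
            f"series {series.series_id!r}: all pseudo-counts zero, ED undefined"
        )
    months = np.array([series.month_of(t) for t in range(series.n)], dtype=float)
    theta = 2.0 * np.pi * months / 12.0
    X = np.column_stack([np.ones_like(theta), np.cos(theta), np.sin(theta)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            null = sm.GLM(y, X[:, :1], family=sm.families.Poisson()).fit()
        except Exception as exc:  # pragma: no cover - statsmodels internals
            raise FitFailureError(
                f"series {series.series_id!r}: ED GLM failed: {exc}"
            ) from exc
    if not (np.all(np.isfinite(full.params)) and np.isfinite(full.llf)):
        raise FitFailureError(f"series {series.series_id!r}: ED GLM did not converge")
    stat = max(0.0, 2.0 * (full.llf - null.llf))
    p = stats.chi2.sf(stat, 2)
    b_cos, b_sin = full.params[1], full.params[2]
    amplitude = float(np.hypot(b_cos, b_sin))
    peak_angle = float(np.arctan2(b_sin, b_cos)) % (2.0 * np.pi)
    peak_month = int(np.round(peak_angle * 12.0 / (2.0 * np.pi))) % 12
    detail = {"amplitude": amplitude, "peak_month": peak_month if peak_month else 12}
    return _result(series, "ED", alpha, stat, 2, p, detail)


# ---------------------------------------------------------------------------
# FR / KW / WE: month-group tests on detrended values
# ---------------------------------------------------------------------------

def _tie_term(x: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(x, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def friedman_test(
    series: ProportionSeries, alpha: float, config: TestConfig = DEFAULT_CONFIG
) -> TestResult:
    """Friedman rank test: years are blocks, the 12 months are treatments.

    Within each year the detrended values are ranked (average ranks on
    ties); the tie-corrected chi-square statistic with 11 df tests the null
    of no month effect.  A fully tied series yields statistic 0, p = 1.
    """
    e = config.detrend_series(series, rank_safe=True)
    mat = fold_year_month(e)
    n_years, k = mat.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, mat)
    R = ranks.sum(axis=0)
    chi = 12.0 / (n_years * k * (k + 1)) * float(R @ R) - 3.0 * n_years * (k + 1)
    ties = sum(_tie_term(row) for row in mat)
    c = 1.0 - ties / (n_years * k * (k**2 - 1))
    if c <= 0.0:
        return _result(series, "FR", alpha, 0.0, k - 1, 1.0)
    stat = max(0.0, chi / c)
    p = stats.chi2.sf(stat, k - 1)
    return _result(series, "FR", alpha, stat, k - 1, p)


def kruskal_wallis_test(
    series: ProportionSeries, alpha: float, config: TestConfig = DEFAULT_CONFIG
) -> TestResult:
    """Kruskal-Wallis rank test across the 12 calendar-month groups.

    All detrended observations are ranked together; the tie-corrected H
    statistic with 11 df tests equality of the month distributions.
    """
    e = config.detrend_series(series, rank_safe=True)
    mat = fold_year_month(e)
    n_years, k = mat.shape
    N = mat.size
    flat = mat.ravel()
    ranks = stats.rankdata(flat).reshape(mat.shape)
    R = ranks.sum(axis=0)  # per-month rank sums; group sizes all n_years
    H = 12.0 / (N * (N + 1)) * float(np.sum(R**2) / n_years) - 3.0 * (N + 1)
    c = 1.0 - _tie_term(flat) / (N**3 - N)
    if c <= 0.0:
        return _result(series, "KW", alpha, 0.0, k - 1, 1.0)
    stat = max(0.0, H / c)
    p = stats.chi2.sf(stat, k - 1)
    return _result(series, "KW", alpha, stat, k - 1, p)


def welch_test(
    series: ProportionSeries, alpha: float, config: TestConfig = DEFAULT_CONFIG
) -> TestResult:
    """Welch one-way ANOVA across month groups, unequal variances allowed.

    F* = [sum w_j (xbar_j - xbar_w)^2 / (k-1)] /
         [1 + 2(k-2)/(k^2-1) * sum h_j],  w_j = n_j / s_j^2,
    h_j = (1 - w_j/sum w)^2 / (n_j - 1),  df2 = (k^2-1) / (3 sum h_j).
    A month group with zero variance makes the weights undefined.
    """
    e = config.detrend_series(series, rank_safe=True)
    mat = fold_year_month(e)
    n_years, k = mat.shape
    n_j = np.full(k, n_years, dtype=float)
    means = mat.mean(axis=0)
    variances = mat.var(axis=0, ddof=1)
    if np.any(variances <= 0.0):
        month = int(np.argmin(variances)) + 1
        raise DegenerateSeriesError(
            f"series {series.series_id!r}: month {month} has zero variance, "
            f"Welch weights undefined"
        )
    w = n_j / variances
    sw = w.sum()
    xw = float(w @ means / sw)
    h = (1.0 - w / sw) ** 2 / (n_j - 1.0)
    sh = float(h.sum())
    num = float(w @ (means - xw) ** 2) / (k - 1)
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * sh
    fstat = num / den
    df1 = k - 1
    df2 = (k**2 - 1) / (3.0 * sh)
    p = stats.f.sf(fstat, df1, df2)
    return _result(series, "WE", alpha, fstat, df1, p, {"df2": float(df2)})


# ---------------------------------------------------------------------------
# QS: seasonal-lag autocorrelation
# ---------------------------------------------------------------------------

def qs_test(
    series: ProportionSeries, alpha: float, config: TestConfig = DEFAULT_CONFIG
) -> TestResult:
    """QS test: Ljung-Box-weighted positive autocorrelations at lags 12, 24.

    QS = n(n+2) * sum_i max(0, rho_{12i})^2 / (n - 12i), i = 1, 2; referred
    to chi-square with 2 df.  Negative seasonal autocorrelations are
    truncated at zero, so QS = 0 (p = 1) when both are non-positive.
    """
    e = config.detrend_series(series)
    n = e.n
    if n <= 24:
        raise ValueError(f"series {series.series_id!r}: QS requires n > 24")
    rho12 = sample_autocorrelation(e, 12)
    rho24 = sample_autocorrelation(e, 24)
    stat = n * (n + 2.0) * (
        max(0.0, rho12) ** 2 / (n - 12) + max(0.0, rho24) ** 2 / (n - 24)
    )
    p = stats.chi2.sf(stat, 2)
    return _result(series, "QS", alpha, stat, 2, p, {"rho12": rho12, "rho24": rho24})


# ---------------------------------------------------------------------------
# ET / AR / AA live in statespace.py; re-exported here for the battery
# ---------------------------------------------------------------------------

def ets_lrt_test(series, alpha, config=DEFAULT_CONFIG):
    from .statespace import ets_lrt_test as _impl

    return _impl(series, alpha, config)


def arima_lrt_test(series, alpha, config=DEFAULT_CONFIG):
    from .statespace import arima_lrt_test as _impl

    return _impl(series, alpha, config)


def auto_arima_test(series, alpha, config=DEFAULT_CONFIG):
    from .statespace import auto_arima_test as _impl

    return _impl(series, alpha, config)


_DISPATCH = {
    "ED": edwards_test,
    "FR": friedman_test,
    "AR": arima_lrt_test,
    "QS": qs_test,
    "ET": ets_lrt_test,
    "KW": kruskal_wallis_test,
    "WE": welch_test,
    "AA": auto_arima_test,
}


def run_method(
    series: ProportionSeries,
    method: str,
    alpha: float,
    config: TestConfig = DEFAULT_CONFIG,
) -> TestResult:
    """Run one method, capturing degenerate-input and fit failures as results."""
    try:
        return _DISPATCH[method](series, alpha, config)
    except (DegenerateSeriesError, FitFailureError, ValueError) as exc:
        return TestResult(
            series_id=series.series_id,
            method=method,
            alpha=alpha,
            seasonal=None,
            error=f"{type(exc).__name__}: {exc}",
        )


def classify_all(
    series: ProportionSeries,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    config: TestConfig = DEFAULT_CONFIG,
    methods: Sequence[str] = METHODS,
) -> list[TestResult]:
    """Run the battery: every method at every significance level.

    The expensive model fits are performed once per method; per-alpha
    verdicts are re-derived from the p-value (AA's alpha-free verdict is
    replicated).  Per-method failures are carried as annotated results,
    never dropped.
    """
    out: list[TestResult] = []
    base_alpha = max(alphas)
    for method in methods:
        base = run_method(series, method, base_alpha, config)
        for alpha in alphas:
            if alpha == base_alpha:
                out.append(base)
            elif base.error is not None or base.p_value is None:
                out.append(replace(base, alpha=alpha))
            else:
                out.append(
                    replace(base, alpha=alpha, seasonal=bool(base.p_value < alpha))
                )
    return out


def results_to_frame(results: Iterable[TestResult]) -> pd.DataFrame:
    """Long-format results table (the delimited-text export layout)."""
    rows = []
    for r in results:
        detail = ";".join(f"{k}={v}" for k, v in sorted(r.detail.items()))
        rows.append(
            (
                r.series_id,
                r.method,
                r.alpha,
                r.statistic,
                r.df,
                r.p_value,
                r.seasonal,
                r.error or "",
                detail,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "series_id",
            "method",
            "alpha",
            "statistic",
            "df",
            "p_value",
            "seasonal",
            "error_flag",
            "detail",
        ],
    )
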