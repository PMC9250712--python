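"""Shared preprocessing: linear detrending, year-by-month folding, autocorrelation.

Seven of the eight classification methods remove any linear-in-time trend
before testing; the detrended residual series is the common substrate of the
rank tests (year-by-month folding) and the seasonal-lag autocorrelation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import ProportionSeries

__all__ = [
    "DetrendedSeries",
    "DegenerateSeriesError",
    "detrend_linear",
    "detrend_difference",
    "fold_year_month",
    "sample_autocorrelation",
]


class DegenerateSeriesError(ValueError):
    """Operation undefined on a (near-)constant series."""


@dataclass
class DetrendedSeries:
    """Residuals e_t of an OLS line fit value_t = a + b*t + e_t (t = 1..n).

    Residuals are orthogonal to the intercept and the time index; the
    seasonal period stays 12.
    """

    values: np.ndarray
    source_id: str
    period: int = 12

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.size


def _as_values(series) -> tuple[np.ndarray, str]:
    if isinstance(series, ProportionSeries):
        return series.values, series.series_id
    if isinstance(series, DetrendedSeries):
        return series.values, series.source_id
    return np.asarray(series, dtype=float), "<array>"


def detrend_linear(series) -> DetrendedSeries:
    """OLS residuals of a straight-line fit against t = 1..n.

    Idempotent: detrending an already-detrended series returns it unchanged
    (up to numerical tolerance), and adding any a + b*t to the input leaves
    the result invariant.
    """
    y, sid = _as_values(series)
    n = y.size
    if n < 3:
        raise ValueError("detrending requires at least 3 observations")
    t = np.arange(1, n + 1, dtype=float)
    tc = t - t.mean()
    b = (tc @ (y - y.mean())) / (tc @ tc)
    a = y.mean() - b * t.mean()
    e = y - (a + b * t)
    # a series that IS a line leaves only floating-point residue, whose
    # systematic rounding pattern would read as spurious structure to the
    # rank and autocorrelation tests; snap it to an exact zero
    if np.max(np.abs(e)) <= 1e-10 * max(1.0, float(np.max(np.abs(y)))):
        e = np.zeros_like(e)
    return DetrendedSeries(values=e, source_id=sid)


def detrend_difference(series) -> DetrendedSeries:
    """First differences, an alternative trend-removal mode.

    Some reference implementations difference rather than regress out the
    trend; exposed for sensitivity analysis.  Note the result has length
    n - 1 and is no longer aligned to complete calendar years.
    """
    y, sid = _as_values(series)
    if y.size < 2:
        raise ValueError("differencing requires at least 2 observations")
    return DetrendedSeries(values=np.diff(y), source_id=sid)


def fold_year_month(series) -> np.ndarray:
    """Reshape a complete-year series into a (years x 12) matrix.

    Row i is the i-th complete year; column j collects every observation of
    calendar month j+1.  Row-major flattening is the inverse.
    """
    y, sid = _as_values(series)
    if y.size % 12 != 0:
        raise ValueError(
            f"series {sid!r}: length {y.size} is not a multiple of 12"
        )
    return y.reshape(-1, 12)


def sample_autocorrelation(series, lag: int) -> float:
    """Biased (n-denominator) sample autocorrelation at the given lag.

    rho_k = sum_{t=1..n-k} (e_t - m)(e_{t+k} - m) / sum_t (e_t - m)^2 with
    m the series mean.  Undefined (raises) on a zero-variance series.
    """
    e, sid = _as_values(series)
    n = e.size
    if not 0 <= lag < n:
        raise ValueError(f"lag must satisfy 0 <= lag < n ({lag=}, {n=})")
    d = e - e.mean()
    denom = d @ d
    if denom <= 0.0:
        raise DegenerateSeriesError(
            f"series {sid!r}: zero variance, autocorrelation undefined"
        )
    if lag == 0:
        return 1.0
    return float((d[:-lag] @ d[lag:]) / denom)
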