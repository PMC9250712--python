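"""Model-based seasonality tests: ETS and ARIMA likelihood-ratio tests and
stepwise auto-ARIMA selection.

All three methods operate on the linearly detrended series.  ETS models are
fit with statsmodels' exponential-smoothing state-space machinery; ARIMA
likelihoods come from the SARIMAX Kalman filter.  Model selection uses the
small-sample-corrected AIC (AICc); the seasonal search mirrors the
Hyndman-Khandakar stepwise algorithm: seasonal differencing order chosen by
an STL seasonal-strength heuristic, ordinary differencing by sequential
KPSS tests, then a greedy neighbourhood walk over (p, q, P, Q) and the
constant term.

A detrended series with (numerically) zero variance is trivially
non-seasonal: likelihood comparison is degenerate there, so these tests
short-circuit to a non-seasonal verdict rather than failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import DetrendedSeries
from .series import ProportionSeries

__all__ = [
    "ArimaOrder",
    "ets_lrt_test",
    "arima_lrt_test",
    "auto_arima_test",
    "stepwise_auto_arima",
    "seasonal_strength",
]

#: seasonal-strength threshold above which one seasonal difference is taken
SEASONAL_STRENGTH_THRESHOLD = 0.64

_ZERO_VAR = 1e-14


@dataclass(frozen=True)
class ArimaOrder:
    """Non-seasonal (p, d, q) and seasonal (P, D, Q) orders at period 12."""

    p: int = 0
    d: int = 0
    q: int = 0
    P: int = 0
    D: int = 0
    Q: int = 0
    constant: bool = True

    def __str__(self):
        c = "c" if self.constant else "0"
        return f"({self.p},{self.d},{self.q})({self.P},{self.D},{self.Q})[12]{c}"

    @property
    def is_seasonal(self) -> bool:
        return (self.P, self.D, self.Q) != (0, 0, 0)


def _residual_variance_zero(e: np.ndarray) -> bool:
    scale = float(np.max(np.abs(e))) if e.size else 0.0
    return float(np.var(e)) <= _ZERO_VAR * max(1.0, scale * scale)


def _trivial_result(series, method, alpha, detail):
    from .methods import TestResult

    return TestResult(
        series_id=series.series_id,
        method=method,
        alpha=alpha,
        seasonal=False,
        statistic=0.0,
        df=None,
        p_value=None if method == "AA" else 1.0,
        detail=detail,
    )


# ---------------------------------------------------------------------------
# ETS likelihood-ratio test
# ---------------------------------------------------------------------------

def _fit_ets(y: np.ndarray, trend, damped, seasonal: bool):
    from statsmodels.tsa.exponential_smoothing.ets import ETSModel

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = ETSModel(
                y,
                error="add",
                trend=trend,
                damped_trend=damped,
                seasonal="add" if seasonal else None,
                seasonal_periods=12 if seasonal else None,
            )
            res = model.fit(disp=0)
        except Exception:
            return None
    if not np.isfinite(res.llf):
        return None
    return res


def _ets_candidates(damped_allowed: bool):
    cands = [(None, False), ("add", False)]
    if damped_allowed:
        cands.append(("add", True))
    return cands


def _aicc_from(llf: float, k: int, n: int) -> float:
    aic = -2.0 * llf + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def ets_lrt_test(series: ProportionSeries, alpha: float, config) -> "TestResult":
    """Likelihood-ratio test of additive seasonality in an ETS model.

    The best additive-error model with additive period-12 seasonality and
    the best without (each chosen by AICc over the candidate trend
    structures) are compared; 2*(llf_seasonal - llf_nonseasonal), clamped
    at zero, is referred to chi-square with df equal to the difference in
    free parameters (the redundant 12th initial seasonal state does not
    count: with matching trend structures df = 12, one seasonal smoothing
    weight plus 11 free initial states).
    """
    from .methods import FitFailureError, _result

    e = config.detrend_series(series)
    y = e.values
    if _residual_variance_zero(y):
        return _trivial_result(series, "ET", alpha, {"note": "zero-variance residuals"})

    def best(seasonal: bool):
        fits = []
        for trend, damped in _ets_candidates(config.ets_damped):
            res = _fit_ets(y, trend, damped, seasonal)
            if res is None:
                continue
            k = len(res.params) + 1  # + innovation variance
            fits.append((_aicc_from(res.llf, k, y.size), res, trend, damped))
        if not fits:
            raise FitFailureError(
                f"series {series.series_id!r}: all ETS "
                f"{'seasonal' if seasonal else 'non-seasonal'} fits failed"
            )
        return min(fits, key=lambda f: f[0])

    _, res_s, trend_s, damped_s = best(True)
    _, res_n, trend_n, damped_n = best(False)
    stat = max(0.0, 2.0 * (res_s.llf - res_n.llf))
    df = max(1, (len(res_s.params) - 1) - len(res_n.params))
    p = stats.chi2.sf(stat, df)
    detail = {
        "seasonal_model": f"AA{'d' if damped_s else ''}{'A' if trend_s else 'N'}A",
        "nonseasonal_model": f"AA{'d' if damped_n else ''}{'A' if trend_n else 'N'}N",
        "k_seasonal": len(res_s.params) + 1,
        "k_nonseasonal": len(res_n.params) + 1,
    }
    return _result(series, "ET", alpha, stat, df, p, detail)


# ---------------------------------------------------------------------------
# SARIMAX fitting and the stepwise search
# ---------------------------------------------------------------------------

def _fit_sarimax(y: np.ndarray, order: ArimaOrder):
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    trend = "c" if order.constant else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = SARIMAX(
                y,
                order=(order.p, order.d, order.q),
                seasonal_order=(order.P, order.D, order.Q, 12),
                trend=trend,
                concentrate_scale=True,
            )
            res = model.fit(disp=0, method="lbfgs", maxiter=100)
        except Exception:
            return None
    if not (np.isfinite(res.llf) and np.all(np.isfinite(res.params))):
        return None
    return res


def _n_params(order: ArimaOrder) -> int:
    # AR/MA coefficients + constant + innovation variance
    return (
        order.p + order.q + order.P + order.Q + (1 if order.constant else 0) + 1
    )


def _aicc(res, order: ArimaOrder, n_eff: int) -> float:
    return _aicc_from(res.llf, _n_params(order), n_eff)


def seasonal_strength(y: np.ndarray, period: int = 12) -> float:
    """Seasonal strength F_s = max(0, 1 - Var(R)/Var(S+R)).

    Computed from a periodic decomposition: linear trend removed, the
    seasonal component taken as the calendar-month means, R the remainder.
    (An STL decomposition with a local seasonal window badly overestimates
    strength on few-cycle series: its seasonal component tracks noise year
    to year.  With only 4-8 cycles the periodic month-mean decomposition
    is the calibrated choice; on white noise it absorbs only ~(period-1)/n
    of the variance.)
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2 * period or _residual_variance_zero(y):
        return 0.0
    t = np.arange(y.size, dtype=float)
    tc = t - t.mean()
    detr = y - y.mean() - (tc @ y) / (tc @ tc) * tc
    month = np.arange(y.size) % period
    seas = np.zeros_like(detr)
    for j in range(period):
        seas[month == j] = detr[month == j].mean()
    resid = detr - seas
    denom = float(np.var(detr))
    if denom <= 0.0:
        return 0.0
    return max(0.0, 1.0 - float(np.var(resid)) / denom)


def _kpss_d(y: np.ndarray, max_d: int = 2, alpha: float = 0.05) -> int:
    """Ordinary differencing order via sequential KPSS level-stationarity tests."""
    from statsmodels.tsa.stattools import kpss

    d = 0
    x = np.asarray(y, dtype=float)
    while d < max_d:
        if _residual_variance_zero(x):
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                _, pval, *_ = kpss(x, regression="c", nlags="auto")
            except Exception:
                break
        if pval >= alpha:
            break
        x = np.diff(x)
        d += 1
    return d


def _neighbours(order: ArimaOrder, config, seasonal: bool) -> list[ArimaOrder]:
    from dataclasses import replace as _rep

    out = []

    def push(**kw):
        cand = _rep(order, **kw)
        if 0 <= cand.p <= config.max_p and 0 <= cand.q <= config.max_q and (
            0 <= cand.P <= config.max_P and 0 <= cand.Q <= config.max_Q
        ):
            out.append(cand)

    for dp in (-1, 1):
        push(p=order.p + dp)
        push(q=order.q + dp)
        push(p=order.p + dp, q=order.q + dp)
    if seasonal:
        for dP in (-1, 1):
            push(P=order.P + dP)
            push(Q=order.Q + dP)
            push(P=order.P + dP, Q=order.Q + dP)
    push(constant=not order.constant)
    return out


def stepwise_auto_arima(
    y: np.ndarray,
    config,
    seasonal: bool,
    d: int | None = None,
    D: int | None = None,
):
    """Greedy stepwise AICc search over SARIMA orders (Hyndman-Khandakar).

    Returns (best_order, best_fit).  When ``seasonal`` is False the search
    is confined to non-seasonal models (P = D = Q = 0).  Differencing
    orders are chosen up-front: D by the seasonal-strength heuristic, d by
    sequential KPSS tests on the (seasonally differenced) series.
    """
    y = np.asarray(y, dtype=float)
    if seasonal and D is None:
        D = 1 if seasonal_strength(y) >= SEASONAL_STRENGTH_THRESHOLD else 0
    D = D or 0
    yd = y[12:] - y[:-12] if D else y
    if d is None:
        d = _kpss_d(yd)
    n_eff = y.size  # common n for AICc comparability across orders

    const0 = (d + D) < 2
    starts = [
        ArimaOrder(2, d, 2, 1 if seasonal else 0, D, 1 if seasonal else 0, const0),
        ArimaOrder(0, d, 0, 0, D, 0, const0),
        ArimaOrder(1, d, 0, 1 if seasonal else 0, D, 0, const0),
        ArimaOrder(0, d, 1, 0, D, 1 if seasonal else 0, const0),
    ]
    starts = [
        o
        for o in starts
        if o.p <= config.max_p
        and o.q <= config.max_q
        and o.P <= config.max_P
        and o.Q <= config.max_Q
    ]

    evaluated: dict[ArimaOrder, float] = {}
    fits: dict[ArimaOrder, object] = {}

    def score(order: ArimaOrder) -> float:
        if order in evaluated:
            return evaluated[order]
        res = _fit_sarimax(y, order)
        val = np.inf if res is None else _aicc(res, order, n_eff)
        evaluated[order] = val
        if res is not None:
            fits[order] = res
        return val

    best = min(starts, key=score)
    if not np.isfinite(evaluated[best]):
        # fall back to white noise without constant
        fallback = ArimaOrder(0, d, 0, 0, D, 0, False)
        score(fallback)
        best = min(evaluated, key=evaluated.get)
        if not np.isfinite(evaluated[best]):
            return None, None

    improved = True
    while improved:
        improved = False
        for cand in _neighbours(best, config, seasonal):
            if score(cand) < evaluated[best]:
                best = cand
                improved = True
                break
    return best, fits.get(best)


# ---------------------------------------------------------------------------
# AR: nested seasonal-augmentation likelihood-ratio test
# ---------------------------------------------------------------------------

#: seasonal augmentations tried on top of the selected non-seasonal order
_AUGMENTATIONS = ((1, 0), (0, 1), (1, 1))


def arima_lrt_test(series: ProportionSeries, alpha: float, config) -> "TestResult":
    """Likelihood-ratio test of a seasonal ARIMA augmentation.

    The non-seasonal order (p, d, q) is selected by stepwise AICc search
    with seasonal terms disabled; the seasonal augmentations
    (P, Q) in {(1,0), (0,1), (1,1)} at D = 0 are fit on the same data and
    the best by AICc is compared to the base by a chi-square LRT with
    df = P + Q.  Optimization noise that leaves the larger model below the
    base clamps the statistic at zero.
    """
    from dataclasses import replace as _rep

    from .methods import FitFailureError, _result

    e = config.detrend_series(series)
    y = e.values
    if _residual_variance_zero(y):
        return _trivial_result(series, "AR", alpha, {"note": "zero-variance residuals"})

    base_order, base_fit = stepwise_auto_arima(y, config, seasonal=False)
    if base_fit is None:
        raise FitFailureError(
            f"series {series.series_id!r}: non-seasonal ARIMA selection failed"
        )

    n_eff = y.size
    best = None
    for P, Q in _AUGMENTATIONS:
        order = _rep(base_order, P=P, D=0, Q=Q)
        res = _fit_sarimax(y, order)
        if res is None:
            continue
        aicc = _aicc(res, order, n_eff)
        if best is None or aicc < best[0]:
            best = (aicc, order, res)
    if best is None:
        raise FitFailureError(
            f"series {series.series_id!r}: all seasonal ARIMA augmentations failed"
        )
    _, aug_order, aug_fit = best
    stat = max(0.0, 2.0 * (aug_fit.llf - base_fit.llf))
    df = aug_order.P + aug_order.Q
    p = stats.chi2.sf(stat, df)
    detail = {"base_order": str(base_order), "augmented_order": str(aug_order)}
    return _result(series, "AR", alpha, stat, df, p, detail)


# ---------------------------------------------------------------------------
# AA: seasonal order selection
# ---------------------------------------------------------------------------

def auto_arima_test(series: ProportionSeries, alpha: float, config) -> "TestResult":
    """Auto-ARIMA selection test: seasonal iff the chosen model is seasonal.

    Runs the stepwise search over seasonal and non-seasonal SARIMA models
    at period 12 and flags the series seasonal when the selected
    (P, D, Q) differs from (0, 0, 0).  There is no p-value; the verdict is
    identical at every significance level.
    """
    from .methods import FitFailureError, TestResult

    e = config.detrend_series(series)
    y = e.values
    if _residual_variance_zero(y):
        return _trivial_result(
            series, "AA", alpha, {"order": str(ArimaOrder()), "note": "zero variance"}
        )
    order, fit = stepwise_auto_arima(y, config, seasonal=True)
    if order is None:
        raise FitFailureError(
            f"series {series.series_id!r}: auto-ARIMA search found no fittable model"
        )
    return TestResult(
        series_id=series.series_id,
        method="AA",
        alpha=alpha,
        seasonal=order.is_seasonal,
        statistic=None,
        df=None,
        p_value=None,
        detail={"order": str(order)},
    )
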