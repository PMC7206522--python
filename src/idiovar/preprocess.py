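"""Per-series preprocessing: Kalman-smoothing imputation and stationarity.

Missing entries are imputed strictly univariately — the imputation model for a
series sees only that series, never the companion series, so no cross-series
correlation can be introduced by the imputation itself.  A small grid of
ARIMA(p, d, q) models (cast to state-space form) is fitted to the observed
series, the best model by information criterion is kept, and missing entries
are replaced by the Kalman-smoothed expectation of the observation process
given the whole observed series.

Stationarity is then obtained by differencing: the smallest d in {0, 1, 2}
for which an ADF/KPSS test pair agrees on stationarity at the chosen level.
Both series of a patient are decided independently, but before VAR fitting
the pair is differenced to the maximum d of the two so the equations share a
time index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.stattools import adfuller, kpss
from statsmodels.tsa.statespace.sarimax import SARIMAX

__all__ = [
    "ImputationReport",
    "FilterSpec",
    "kalman_impute",
    "stationarity_filter",
    "filter_pair",
    "prepare_pair",
]

MIN_OBSERVED = 30

#: ARIMA order grid searched by the imputation model: AR 0–3, d 0–1, MA 0–1
DEFAULT_ORDER_GRID = tuple(
    (p, d, q) for p in range(4) for d in range(2) for q in range(2)
)


@dataclass
class ImputationReport:
    """What the imputation did to one series."""

    variable: str
    order: tuple[int, int, int]
    positions: np.ndarray
    values: np.ndarray
    aic: float = float("nan")
    fallback_constant: bool = False


@dataclass
class FilterSpec:
    """Differencing decision for one series, with the test evidence."""

    variable: str
    d: int
    applied_d: int | None = None
    detrended: bool = False
    tests: dict = field(default_factory=dict)  # per d: {'adf_p':…, 'kpss_p':…}


def _check_input(values: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    observed = ~np.isnan(x)
    if observed.sum() == 0:
        raise ValueError(f"{name}: series is entirely missing")
    if observed.sum() < MIN_OBSERVED:
        raise ValueError(
            f"{name}: only {int(observed.sum())} observed values; "
            f"at least {MIN_OBSERVED} required for imputation"
        )
    return x


def kalman_impute(
    values: np.ndarray,
    variable: str = "series",
    order_grid: tuple = DEFAULT_ORDER_GRID,
) -> tuple[np.ndarray, ImputationReport]:
    """Fill missing entries via the Kalman smoother of a selected ARIMA model.

    The model is selected on the observed series by AIC over ``order_grid``
    (each candidate fitted with a constant term, which becomes a drift under
    differencing).  Observed entries are never altered.  A flat observed
    series cannot support a stochastic model and falls back to a constant
    fill with a warning.
    """
    x = _check_input(values, variable)
    missing = np.isnan(x)
    positions = np.flatnonzero(missing)
    if positions.size == 0:
        return x.copy(), ImputationReport(variable, (0, 0, 0), positions, np.array([]))

    observed_vals = x[~missing]
    if np.ptp(observed_vals) == 0.0:
        warnings.warn(
            f"{variable}: observed series is constant; falling back to constant fill"
        )
        out = x.copy()
        out[missing] = observed_vals[0]
        return out, ImputationReport(
            variable, (0, 0, 0), positions, out[positions].copy(),
            fallback_constant=True,
        )

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for order in order_grid:
            try:
                res = SARIMAX(x, order=order, trend="c").fit(disp=0)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isnan(res.aic):
                continue
            if best is None or res.aic < best[1]:
                best = (order, res.aic, res)
    if best is None:
        raise RuntimeError(f"{variable}: no ARIMA candidate could be fitted")
    order, aic, res = best
    smoothed = np.asarray(res.filter_results.smoothed_forecasts[0])
    out = x.copy()
    out[missing] = smoothed[missing]
    return out, ImputationReport(variable, order, positions, out[positions].copy(), aic=aic)


def _stationary_at(x: np.ndarray, alpha: float) -> tuple[bool, dict]:
    """ADF (unit-root null) and KPSS (stationary null) agreement at ``alpha``."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InterpolationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        adf_stat, adf_p = adfuller(x, autolag="AIC")[:2]
        kpss_stat, kpss_p = kpss(x, regression="c", nlags="auto")[:2]
    ok = (adf_p <= alpha) and (kpss_p >= alpha)
    return ok, {
        "adf_stat": float(adf_stat),
        "adf_p": float(adf_p),
        "kpss_stat": float(kpss_stat),
        "kpss_p": float(kpss_p),
    }


def stationarity_filter(
    values: np.ndarray,
    variable: str = "series",
    alpha: float = 0.05,
    max_d: int = 2,
    detrend: bool = False,
) -> tuple[np.ndarray, FilterSpec]:
    """Difference a complete series to stationarity.

    Chooses the smallest d ∈ {0..max_d} at which the ADF test rejects a unit
    root and the KPSS test does not reject level stationarity, both at
    ``alpha``.  With ``detrend=True`` an ordinary-least-squares linear
    detrend is tried before first differencing.
    """
    x = np.asarray(values, dtype=float).ravel()
    if np.isnan(x).any():
        raise ValueError(f"{variable}: impute before filtering (NaNs present)")
    if np.ptp(x) == 0.0:
        raise ValueError(f"{variable}: constant series has no variance to model")

    spec = FilterSpec(variable=variable, d=0)
    work = x
    ok, stats = _stationary_at(work, alpha)
    spec.tests[0] = stats
    if ok:
        spec.applied_d = 0
        return work.copy(), spec

    if detrend:
        t = np.arange(x.size, dtype=float)
        beta = np.polyfit(t, x, 1)
        resid = x - np.polyval(beta, t)
        ok, stats = _stationary_at(resid, alpha)
        spec.tests["detrend"] = stats
        if ok:
            spec.detrended = True
            spec.applied_d = 0
            return resid, spec

    for d in range(1, max_d + 1):
        work = np.diff(x, n=d)
        ok, stats = _stationary_at(work, alpha)
        spec.tests[d] = stats
        if ok:
            spec.d = d
            spec.applied_d = d
            return work.copy(), spec
    raise ValueError(
        f"{variable}: still non-stationary after differencing to order {max_d}"
    )


def filter_pair(
    a: np.ndarray,
    b: np.ndarray,
    names: tuple[str, str] = ("sleep", "depression"),
    alpha: float = 0.05,
    max_d: int = 2,
    detrend: bool = False,
) -> tuple[np.ndarray, np.ndarray, FilterSpec, FilterSpec]:
    """Filter two complete series to a shared stationary index.

    Each series' differencing order is decided independently; both are then
    differenced to the maximum of the two (recorded as ``applied_d``) so the
    VAR sees jointly indexed inputs.
    """
    fa, sa = stationarity_filter(a, names[0], alpha=alpha, max_d=max_d, detrend=detrend)
    fb, sb = stationarity_filter(b, names[1], alpha=alpha, max_d=max_d, detrend=detrend)
    d_common = max(sa.applied_d, sb.applied_d)
    if sa.detrended or sb.detrended:
        # a detrended series keeps full length; align by trimming the head
        n = min(fa.size, fb.size)
        fa, fb = fa[-n:], fb[-n:]
    else:
        if sa.applied_d < d_common:
            fa = np.diff(np.asarray(a, dtype=float), n=d_common)
            sa.applied_d = d_common
        if sb.applied_d < d_common:
            fb = np.diff(np.asarray(b, dtype=float), n=d_common)
            sb.applied_d = d_common
    return fa, fb, sa, sb


def prepare_pair(
    a: np.ndarray,
    b: np.ndarray,
    names: tuple[str, str] = ("sleep", "depression"),
    alpha: float = 0.05,
    max_d: int = 2,
    detrend: bool = False,
    order_grid: tuple = DEFAULT_ORDER_GRID,
):
    """Impute then stationarity-filter a pair of aligned daily series.

    Returns ``(ya, yb, info)`` where ``info`` carries the two imputation
    reports and filter specs.
    """
    ia, ra = kalman_impute(a, names[0], order_grid=order_grid)
    ib, rb = kalman_impute(b, names[1], order_grid=order_grid)
    fa, fb, sa, sb = filter_pair(ia, ib, names, alpha=alpha, max_d=max_d, detrend=detrend)
    info = {"imputation": (ra, rb), "filters": (sa, sb)}
    return fa, fb, info
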