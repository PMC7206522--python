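"""Bivariate VAR estimation, lag selection and Granger causality.

The model is the workhorse of the idiographic pipeline: for one patient, a
pair of stationary daily series y_t = (sleep_t, depression_t)' follows

    y_t = c + A_1 y_{t-1} + … + A_p y_{t-p} + ε_t,   ε_t ~ (0, Σ),

estimated equation by equation with ordinary least squares.  The lag order p
is chosen by the Akaike information criterion over candidates 1..7 (seven
days of memory at most), all candidates being fitted on the sample trimmed to
the maximal lag so their criteria are comparable.  Granger causality is the
F-test of the cross-lag block: past values of the putative cause must improve
the prediction of the effect beyond the effect's own past.

Usage follows the familiar model/results split::

    model = PatientVAR(endog, names=("sleep", "depression"))
    res = model.fit(maxlag=7)
    gc = res.granger("sleep", "depression")
    irf = res.irf("sleep", "depression", bands=True, seed=7)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import dynamics as _dyn
from .dynamics import FevdResult, IrfResult, _lag_design
from .synthetic import companion_matrix, spectral_radius

__all__ = ["PatientVAR", "VARResults", "GrangerResult", "LagSelection"]

DEFAULT_MAXLAG = 7


@dataclass
class GrangerResult:
    """One directed Granger causality test inside a fitted bivariate VAR."""

    cause: str
    effect: str
    statistic: float
    df_num: int
    df_den: int
    p_value: float
    alpha: float
    significant: bool
    association_sign: str  # 'positive' | 'negative'

    def __str__(self) -> str:
        star = "*" if self.significant else ""
        return (
            f"{self.cause} → {self.effect}: F({self.df_num}, {self.df_den}) = "
            f"{self.statistic:.3f}, p = {self.p_value:.4f}{star} "
            f"({self.association_sign})"
        )


@dataclass
class LagSelection:
    """AIC values per candidate lag and the minimizing order."""

    candidates: np.ndarray
    aic: np.ndarray
    selected: int


class PatientVAR:
    """Bivariate VAR model for one patient's aligned stationary series."""

    def __init__(self, endog, names: tuple[str, str] = ("sleep", "depression")):
        y = np.asarray(endog, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("endog must be an (n, 2) array")
        if np.isnan(y).any():
            raise ValueError("endog contains NaN; impute before fitting")
        self.endog = y
        self.names = tuple(names)
        for j, nm in enumerate(self.names):
            if np.ptp(y[:, j]) == 0.0:
                raise ValueError(f"variable {nm!r} is constant; VAR is rank deficient")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, columns: tuple[str, str]):
        return cls(frame.loc[:, list(columns)].to_numpy(dtype=float), names=columns)

    @property
    def nobs(self) -> int:
        return self.endog.shape[0]

    # -- estimation --------------------------------------------------------

    def _ols(self, p: int, trim: int | None = None):
        """Equationwise OLS at lag ``p`` on the sample trimmed to ``trim``."""
        trim = p if trim is None else trim
        y = self.endog[trim - p :]  # drop extra head so rows start at index `trim`
        Y, X = _lag_design(y, p)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                f"rank-deficient regressor matrix at lag {p} "
                f"(rank {rank} < {X.shape[1]})"
            )
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        E = Y - X @ B
        n_eff = Y.shape[0]
        sigma = E.T @ E / n_eff
        return B, E, sigma, n_eff

    @staticmethod
    def _aic(sigma: np.ndarray, n_eff: int, p: int, k: int = 2) -> float:
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf
        return float(logdet + 2.0 * k * (k * p + 1) / n_eff)

    def select_lag(self, maxlag: int = DEFAULT_MAXLAG) -> LagSelection:
        """AIC lag-order selection over candidates 1..maxlag.

        All candidates are fitted on the common sample that drops the first
        ``maxlag`` observations, so the criteria compare like with like.
        """
        if self.nobs < 3 * maxlag:
            raise ValueError(
                f"series of length {self.nobs} too short for maxlag {maxlag} "
                f"(need at least {3 * maxlag})"
            )
        if self.nobs < 10 * maxlag:
            warnings.warn(
                f"series of length {self.nobs} is short for maxlag {maxlag}; "
                "lag selection may be unstable"
            )
        candidates = np.arange(1, maxlag + 1)
        aics = np.empty(candidates.size)
        for i, p in enumerate(candidates):
            _, _, sigma, n_eff = self._ols(int(p), trim=maxlag)
            aics[i] = self._aic(sigma, n_eff, int(p))
        return LagSelection(candidates, aics, int(candidates[np.argmin(aics)]))

    def fit(self, lags: int | None = None, maxlag: int = DEFAULT_MAXLAG) -> "VARResults":
        """Estimate the VAR; with ``lags=None`` the order is chosen by AIC."""
        selection = None
        if lags is None:
            selection = self.select_lag(maxlag)
            lags = selection.selected
        if lags < 1:
            raise ValueError("lag order must be >= 1")
        if self.nobs <= 2 * (2 * lags + 1):
            raise ValueError(
                f"series of length {self.nobs} too short to fit VAR({lags})"
            )
        B, E, sigma, n_eff = self._ols(lags)
        k = 2
        intercepts = B[0]
        coef = np.stack(
            [B[1 + (lag - 1) * k : 1 + lag * k].T for lag in range(1, lags + 1)]
        )
        sign, logdet = np.linalg.slogdet(sigma)
        log_lik = -0.5 * n_eff * (k * np.log(2 * np.pi) + logdet + k)
        return VARResults(
            model=self,
            p=int(lags),
            intercepts=intercepts,
            coef_matrices=coef,
            resid=E,
            resid_cov=sigma,
            n_effective=n_eff,
            aic=self._aic(sigma, n_eff, lags),
            log_lik=float(log_lik),
            lag_selection=selection,
        )


class VARResults:
    """Estimated VAR(p) with Granger, IRF and FEVD analyses attached."""

    def __init__(
        self,
        model: PatientVAR,
        p: int,
        intercepts: np.ndarray,
        coef_matrices: np.ndarray,
        resid: np.ndarray,
        resid_cov: np.ndarray,
        n_effective: int,
        aic: float,
        log_lik: float,
        lag_selection: LagSelection | None = None,
    ):
        self.model = model
        self.names = model.names
        self.p = p
        self.intercepts = intercepts
        self.coef_matrices = coef_matrices
        self.resid = resid
        self.resid_cov = resid_cov
        self.n_effective = n_effective
        self.aic = aic
        self.log_lik = log_lik
        self.lag_selection = lag_selection

    # -- stability ---------------------------------------------------------

    @property
    def companion(self) -> np.ndarray:
        return companion_matrix(self.coef_matrices)

    @property
    def spectral_radius(self) -> float:
        return spectral_radius(self.coef_matrices)

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0

    # -- Granger causality -------------------------------------------------

    def granger(self, cause: str, effect: str, alpha: float = 0.05) -> GrangerResult:
        """F-test of whether ``cause``'s past improves prediction of ``effect``.

        The restricted model regresses ``effect`` on its own p lags only; the
        unrestricted model adds the p lags of ``cause``.  The association sign
        is the sign of the cumulative orthogonalized impulse response of the
        effect to a cause shock at horizon 10, i.e. whether more of the cause
        is followed by more or by less of the effect overall.
        """
        if cause == effect:
            raise ValueError("cause and effect must differ")
        ci = self.names.index(cause)
        ei = self.names.index(effect)
        p = self.p
        y = self.model.endog
        Y, X = _lag_design(y, p)
        y_eff = Y[:, ei]
        own_cols = [0] + [1 + (lag - 1) * 2 + ei for lag in range(1, p + 1)]
        Xr = X[:, own_cols]
        bu, *_ = np.linalg.lstsq(X, y_eff, rcond=None)
        br, *_ = np.linalg.lstsq(Xr, y_eff, rcond=None)
        rss_u = float(np.sum((y_eff - X @ bu) ** 2))
        rss_r = float(np.sum((y_eff - Xr @ br) ** 2))
        if rss_r < rss_u - 1e-8 * max(rss_u, 1.0):
            raise RuntimeError(
                "restricted RSS below unrestricted RSS: nested OLS violated"
            )
        df_num = p
        df_den = self.n_effective - 2 * p - 1
        if df_den <= 0:
            raise ValueError("not enough observations for the Granger F-test")
        fstat = ((rss_r - rss_u) / df_num) / (rss_u / df_den)
        fstat = max(fstat, 0.0)
        p_value = float(_stats.f.sf(fstat, df_num, df_den))
        irf = self.irf(impulse=cause, response=effect, horizon=10)
        sign = "positive" if irf.cumulative[-1] >= 0 else "negative"
        return GrangerResult(
            cause=cause,
            effect=effect,
            statistic=float(fstat),
            df_num=df_num,
            df_den=df_den,
            p_value=p_value,
            alpha=alpha,
            significant=bool(p_value < alpha),
            association_sign=sign,
        )

    # -- dynamics ----------------------------------------------------------

    def ma_coefficients(self, horizon: int = 10) -> np.ndarray:
        phi = _dyn.ma_coefficients(self.coef_matrices, horizon)
        if not self.is_stable:
            warnings.warn(
                f"fit is not stable (spectral radius {self.spectral_radius:.3f}); "
                "responses may diverge"
            )
        return phi

    def series_sd(self, variable: str) -> float:
        return float(self.model.endog[:, self.names.index(variable)].std(ddof=1))

    def irf(
        self,
        impulse: str,
        response: str,
        horizon: int = 10,
        shock: str = "series_sd",
        ordering: tuple[str, ...] | None = None,
        bands: bool = False,
        runs: int = 500,
        level: float = 0.95,
        seed: int | None = None,
    ) -> IrfResult:
        """Orthogonalized IRF; ``shock='series_sd'`` (default) scales the
        impulse to 1 SD of the impulse series, ``'residual_sd'`` to 1 SD of
        its innovation.  ``bands=True`` attaches bootstrap intervals."""
        if shock == "series_sd":
            shock_sd = self.series_sd(impulse)
        elif shock == "residual_sd":
            imp = self.names.index(impulse)
            shock_sd = float(np.sqrt(self.resid_cov[imp, imp]))
        else:
            raise ValueError("shock must be 'series_sd' or 'residual_sd'")
        res = _dyn.orthogonalized_irf(
            self.coef_matrices,
            self.resid_cov,
            self.names,
            impulse,
            response,
            horizon=horizon,
            shock_sd=shock_sd,
            ordering=ordering,
        )
        if bands:
            bb = _dyn.bootstrap_band(
                self.model.endog,
                self.intercepts,
                self.coef_matrices,
                self.resid,
                impulse,
                response,
                self.names,
                horizon=horizon,
                runs=runs,
                level=level,
                seed=seed,
                ordering=ordering,
                shock=shock,
            )
            # a percentile band can in principle miss the plug-in estimate;
            # widen minimally so the reported interval always contains it
            res.lower = np.minimum(bb["lower"], res.point)
            res.upper = np.maximum(bb["upper"], res.point)
            res.cum_lower = np.minimum(bb["cum_lower"], res.cumulative)
            res.cum_upper = np.maximum(bb["cum_upper"], res.cumulative)
            res.level = level
            res.boot_completion = bb["completion"]
        return res

    def fevd(
        self,
        horizon: int = 10,
        ordering: tuple[str, ...] | None = None,
    ) -> list[FevdResult]:
        """FEVD for both variables, horizons 1..H (recursive identification,
        variables ordered as in ``names`` — sleep first — unless overridden)."""
        return _dyn.fevd(
            self.coef_matrices,
            self.resid_cov,
            self.names,
            horizon=horizon,
            ordering=ordering,
        )

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"Bivariate VAR({self.p}) — variables: {self.names[0]}, {self.names[1]}",
            f"observations used: {self.n_effective}   AIC: {self.aic:.4f}   "
            f"log-likelihood: {self.log_lik:.2f}",
            f"spectral radius: {self.spectral_radius:.4f} "
            f"({'stable' if self.is_stable else 'UNSTABLE'})",
            "",
            f"{'equation':<14}{'intercept':>12}"
            + "".join(
                f"{nm}[t-{lag}]".rjust(16)
                for lag in range(1, self.p + 1)
                for nm in self.names
            ),
        ]
        for i, nm in enumerate(self.names):
            row = f"{nm:<14}{self.intercepts[i]:>12.4f}"
            for lag in range(self.p):
                for j in range(2):
                    row += f"{self.coef_matrices[lag, i, j]:>16.4f}"
            lines.append(row)
        lines.append("")
        lines.append("residual covariance:")
        for i in range(2):
            lines.append("    " + "  ".join(f"{v:12.4f}" for v in self.resid_cov[i]))
        for cause, effect in ((self.names[0], self.names[1]), (self.names[1], self.names[0])):
            lines.append(str(self.granger(cause, effect)))
        return "\n".join(lines)
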