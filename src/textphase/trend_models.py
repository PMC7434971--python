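"""Trend inference on the charge series: logistic regression of the
inside/outside labels on time, ARIMA modelling of the distance series,
and the accompanying identification/diagnostic tools (ACF/PACF,
Ljung-Box).  Estimation is delegated to statsmodels; this module fixes
the conventions (biased ACF denominator, Durbin-Levinson PACF, the
"+theta" MA sign) and the derived summaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from statsmodels.tsa.stattools import acf as sm_acf, pacf as sm_pacf

from ._utils import as_1d_float
from .exceptions import DegenerateInputError, FitError

__all__ = [
    "LogisticFit",
    "ARIMAFit",
    "CorrelogramResult",
    "fit_logistic_trend",
    "acf_pacf",
    "fit_arima",
    "ljung_box",
]


@dataclass(frozen=True)
class LogisticFit:
    """Binary logistic regression of class membership on a predictor."""

    beta_time: float
    beta_const: float
    se_time: float
    se_const: float
    wald_time: float
    wald_const: float
    p_time: float
    p_const: float
    or_time: float
    or_const: float
    lr_chi2: float
    lr_p: float
    concordance_pct: float  # percent correctly classified at cutoff 0.5
    c_statistic: float      # concordant-pairs AUC alternative
    converged: bool = True


def fit_logistic_trend(labels, time=None) -> LogisticFit:
    """Maximum-likelihood logistic fit of P(second class) on time.

    Parameters
    ----------
    labels
        Binary series; the larger value is modelled as the event (for
        centroid labels 1/2 the event is "outside").
    time
        Predictor, default ``1..N``.

    Raises
    ------
    DegenerateInputError
        If only one class is present.
    FitError
        On complete separation or non-convergence (never silent output).
    """
    lab = np.asarray(labels).ravel()
    classes = np.unique(lab)
    if len(classes) < 2:
        raise DegenerateInputError("single class: labels take only one value")
    if len(classes) > 2:
        raise ValueError("labels must be binary")
    y = (lab == classes[1]).astype(float)
    t = np.arange(1, len(y) + 1, dtype=float) if time is None \
        else as_1d_float(time, "time")
    X = sm.add_constant(t)
    try:
        res = sm.Logit(y, X).fit(disp=0)
    except PerfectSeparationError as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False) or \
            not np.all(np.isfinite(res.bse)):
        raise FitError("logistic fit did not converge (possible separation)")

    b_const, b_time = res.params
    se_const, se_time = res.bse
    p = res.predict(X)
    concordance = float(np.mean((p >= 0.5) == (y == 1)) * 100.0)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    u = stats.mannwhitneyu(p[y == 1], p[y == 0]).statistic
    return LogisticFit(
        beta_time=float(b_time), beta_const=float(b_const),
        se_time=float(se_time), se_const=float(se_const),
        wald_time=float((b_time / se_time) ** 2),
        wald_const=float((b_const / se_const) ** 2),
        p_time=float(res.pvalues[1]), p_const=float(res.pvalues[0]),
        or_time=float(np.exp(b_time)), or_const=float(np.exp(b_const)),
        lr_chi2=float(res.llr), lr_p=float(res.llr_pvalue),
        concordance_pct=concordance, c_statistic=float(u / (n1 * n0)),
        converged=True,
    )


@dataclass(frozen=True)
class CorrelogramResult:
    """Sample ACF/PACF for lags 1..L with the 95% white-noise band."""

    acf: np.ndarray
    pacf: np.ndarray
    ci_bound: float

    @property
    def max_lag(self) -> int:
        return len(self.acf)


def acf_pacf(series, max_lag: int) -> CorrelogramResult:
    """Sample ACF (biased, denominator N) and Durbin-Levinson PACF."""
    x = as_1d_float(series)
    n = len(x)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if n <= max_lag + 1:
        raise ValueError(f"need N > max_lag + 1 (N={n}, max_lag={max_lag})")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has zero variance")
    r = sm_acf(x, nlags=max_lag, adjusted=False, fft=False)[1:]
    phi = sm_pacf(x, nlags=max_lag, method="ldb")[1:]
    return CorrelogramResult(r, phi, 1.96 / np.sqrt(n))


@dataclass(frozen=True)
class ARIMAFit:
    """ARIMA(p,d,q) fit with drift, on the "+theta" MA sign convention:
    the model for the differenced series w_t is
    w_t = c + phi*w_{t-1} + eps_t + theta*eps_{t-1}."""

    order: tuple[int, int, int]
    constant: float
    ar1: float
    ma1: float
    ses: dict = field(default_factory=dict)
    t_stats: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    r_squared: float = float("nan")
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    stationary: bool = True
    invertible: bool = True
    ma_sign_convention: str = "+theta"
    aic: float = float("nan")


def fit_arima(series, p: int = 1, d: int = 1, q: int = 1) -> ARIMAFit:
    """Fit an ARIMA(p,d,q) model with a constant/drift term.

    With ``d >= 1`` the deterministic term is a linear trend in levels,
    i.e. a drift of the differenced series (its coefficient reported as
    ``constant``).  ``r_squared`` is the stationary R²:
    ``1 - SSE(residuals) / SST(d-times differenced series)``.

    Non-convergence and non-invertibility are flagged on the result,
    never silently dropped.
    """
    x = as_1d_float(series)
    n = len(x)
    if n - d <= 10:
        raise ValueError(f"need N - d > 10 (N={n}, d={d})")
    trend = "t" if d >= 1 else "c"
    model = sm.tsa.ARIMA(x, order=(p, d, q), trend=trend)
    res = model.fit()

    names = list(res.param_names)
    params = dict(zip(names, res.params))
    bses = dict(zip(names, res.bse))
    pvals = dict(zip(names, res.pvalues))
    trend_name = next(
        (nm for nm in names
         if not nm.startswith(("ar.", "ma.")) and nm != "sigma2"), None)

    def _grab(key):  # (value, se, t, p) per named parameter
        if key is None or key not in params:
            return 0.0, np.nan, np.nan, np.nan
        se = bses[key]
        return (float(params[key]), float(se),
                float(params[key] / se) if se > 0 else np.nan,
                float(pvals[key]))

    const, const_se, const_t, const_p = _grab(trend_name)
    ar1, ar_se, ar_t, ar_p = _grab("ar.L1")
    ma1, ma_se, ma_t, ma_p = _grab("ma.L1")

    resid = np.asarray(res.resid)[d:]
    w = np.diff(x, n=d) if d else x
    sst = float(np.sum((w - w.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else np.nan
    converged = bool(res.mle_retvals.get("converged", True)) \
        if hasattr(res, "mle_retvals") else True
    stationary = bool(np.all(np.abs(res.arroots) > 1)) if p else True
    invertible = bool(np.all(np.abs(res.maroots) > 1)) if q else True

    return ARIMAFit(
        order=(p, d, q), constant=const, ar1=ar1, ma1=ma1,
        ses={"constant": const_se, "ar1": ar_se, "ma1": ma_se},
        t_stats={"constant": const_t, "ar1": ar_t, "ma1": ma_t},
        p_values={"constant": const_p, "ar1": ar_p, "ma1": ma_p},
        r_squared=r2, residuals=resid, converged=converged,
        stationary=stationary, invertible=invertible,
        aic=float(res.aic),
    )


def ljung_box(residuals, lags: int, n_params: int = 0):
    """Ljung-Box portmanteau test on residual autocorrelations.

    ``Q = N(N+2) * sum_{k=1..h} r_k^2 / (N-k)``; degrees of freedom are
    ``h - n_params`` (subtract the number of fitted ARMA parameters).

    Returns
    -------
    (Q, df, p)
    """
    x = as_1d_float(residuals, "residuals")
    n = len(x)
    if lags < 1 or n <= lags:
        raise ValueError(f"need 1 <= lags < N (N={n}, lags={lags})")
    df = lags - n_params
    if df <= 0:
        raise ValueError(f"df = lags - n_params = {df} must be positive")
    tbl = acorr_ljungbox(x, lags=[lags], model_df=0)
    q = float(tbl["lb_stat"].iloc[0])
    p = float(stats.chi2.sf(q, df))
    return q, df, p
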