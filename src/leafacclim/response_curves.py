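"""Temperature-response curve fitting for leaf gas exchange.

Net assimilation measured across the diurnal air-temperature range is fitted
with a parabola,

    A_i = A_opt − b (T_i − T_opt)²,

whose apex gives the photosynthetic optimum (T_opt, A_opt) and whose width
parameter ``b`` yields the thermal breadth

    T_80 = 2 sqrt(0.2 A_opt / b),

the distance between the two temperatures where assimilation falls to 80 % of
A_opt.  Dark respiration is fitted with the exponential Q10 form

    R_i = R_25 · Q_10^((T_i − 25)/10).

Both fits are exposed as scikit-learn style estimators
(:class:`ParabolicTemperatureResponse`, :class:`ExponentialRespirationResponse`)
and as thin table-level functions (:func:`fit_parabolic`,
:func:`fit_exponential`, :func:`fit_curves_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


# ---------------------------------------------------------------------------
# result records


@dataclass
class PhotoTempFit:
    """Fitted parabolic assimilation–temperature response."""

    a_opt: float
    t_opt: float
    b: float
    t80: float
    r_squared: float
    n_points: int
    std_errors: dict = field(default_factory=dict)
    flag: str = "ok"

    @property
    def ok(self) -> bool:
        return self.flag == "ok"

    def predict(self, temperature):
        t = np.asarray(temperature, dtype=float)
        return self.a_opt - self.b * (t - self.t_opt) ** 2


@dataclass
class RespTempFit:
    """Fitted exponential respiration–temperature response."""

    r25: float
    q10: float
    r_squared: float
    n_points: int
    std_errors: dict = field(default_factory=dict)
    flag: str = "ok"

    @property
    def ok(self) -> bool:
        return self.flag == "ok"

    def predict(self, temperature):
        t = np.asarray(temperature, dtype=float)
        return self.r25 * self.q10 ** ((t - 25.0) / 10.0)


def thermal_breadth(a_opt: float, b: float) -> float:
    """Width (°C) of the interval where A(T) > 0.8 A_opt.

    Solving ``A_opt − b (T − T_opt)² = 0.8 A_opt`` for T gives the two roots
    ``T_opt ± sqrt(0.2 A_opt / b)``; their distance is returned.
    """
    if a_opt <= 0 or b <= 0:
        raise ValueError("thermal breadth requires a_opt > 0 and b > 0")
    return 2.0 * np.sqrt(0.2 * a_opt / b)


# ---------------------------------------------------------------------------
# estimators


def _r_squared(y, yhat):
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


class ParabolicTemperatureResponse(BaseEstimator, RegressorMixin):
    """Least-squares parabola A(T) = a_opt − b (T − t_opt)².

    The model is linear in the monomial coefficients (c0, c1, c2) of
    ``c0 + c1 T + c2 T²``, so the global least-squares optimum is found
    exactly by ``numpy.polyfit`` and mapped to the apex parameterization:
    ``b = −c2``, ``t_opt = −c1 / (2 c2)``, ``a_opt = c0 − c1²/(4 c2)``.
    Standard errors come from the linear-coefficient covariance via the
    delta method.

    Fitted attributes: ``a_opt_``, ``t_opt_``, ``b_``, ``t80_``,
    ``r_squared_``, ``std_errors_``, ``n_points_``.
    """

    def __init__(self, min_points: int = 4):
        self.min_points = min_points

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        a = np.asarray(y, dtype=float).ravel()
        if t.size != a.size:
            raise ValueError("temperature and flux arrays differ in length")
        if t.size < self.min_points:
            raise ValueError(
                f"need at least {self.min_points} points, got {t.size}"
            )
        if np.unique(t).size < 3:
            raise ValueError("need at least 3 distinct temperatures")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise ValueError("non-finite inputs")

        c2, c1, c0 = np.polyfit(t, a, 2)
        if c2 >= 0:
            raise ValueError("fitted curvature is non-positive (b <= 0)")
        self.b_ = -float(c2)
        self.t_opt_ = -float(c1) / (2.0 * float(c2))
        self.a_opt_ = float(c0) - float(c1) ** 2 / (4.0 * float(c2))

        yhat = c0 + c1 * t + c2 * t**2
        self.r_squared_ = _r_squared(a, yhat)
        self.n_points_ = int(t.size)
        self.t80_ = (
            thermal_breadth(self.a_opt_, self.b_) if self.a_opt_ > 0 else np.nan
        )
        self.std_errors_ = self._delta_method_se(t, a, (c0, c1, c2))
        return self

    @staticmethod
    def _delta_method_se(t, a, coeffs):
        c0, c1, c2 = coeffs
        n = t.size
        dof = n - 3
        if dof <= 0:
            return {"a_opt": np.nan, "t_opt": np.nan, "b": np.nan}
        design = np.column_stack([np.ones_like(t), t, t**2])
        resid = a - design @ np.array([c0, c1, c2])
        sigma2 = float(resid @ resid) / dof
        cov_c = sigma2 * np.linalg.inv(design.T @ design)
        # gradients of (a_opt, t_opt, b) w.r.t. (c0, c1, c2)
        g_aopt = np.array([1.0, -c1 / (2 * c2), c1**2 / (4 * c2**2)])
        g_topt = np.array([0.0, -1.0 / (2 * c2), c1 / (2 * c2**2)])
        g_b = np.array([0.0, 0.0, -1.0])
        return {
            "a_opt": float(np.sqrt(g_aopt @ cov_c @ g_aopt)),
            "t_opt": float(np.sqrt(g_topt @ cov_c @ g_topt)),
            "b": float(np.sqrt(g_b @ cov_c @ g_b)),
        }

    def predict(self, X):
        check_is_fitted(self, "a_opt_")
        t = np.asarray(X, dtype=float).ravel()
        return self.a_opt_ - self.b_ * (t - self.t_opt_) ** 2

    def result_(self) -> PhotoTempFit:
        check_is_fitted(self, "a_opt_")
        return PhotoTempFit(
            a_opt=self.a_opt_, t_opt=self.t_opt_, b=self.b_, t80=self.t80_,
            r_squared=self.r_squared_, n_points=self.n_points_,
            std_errors=self.std_errors_,
        )


class ExponentialRespirationResponse(BaseEstimator, RegressorMixin):
    """Nonlinear least squares for R(T) = r25 · q10^((T−25)/10).

    Initialized from the log-linear regression of ln R on (T − 25)/10 and
    refined with ``scipy.optimize.curve_fit`` on the original scale (the
    least-squares objective is on R, not ln R).

    Fitted attributes: ``r25_``, ``q10_``, ``r_squared_``, ``std_errors_``,
    ``n_points_``.
    """

    def __init__(self, min_points: int = 3):
        self.min_points = min_points

    @staticmethod
    def _model(t, r25, q10):
        return r25 * q10 ** ((t - 25.0) / 10.0)

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        r = np.asarray(y, dtype=float).ravel()
        if t.size != r.size:
            raise ValueError("temperature and flux arrays differ in length")
        if t.size < self.min_points:
            raise ValueError(
                f"need at least {self.min_points} points, got {t.size}"
            )
        if np.unique(t).size < 2:
            raise ValueError("need at least 2 distinct temperatures")
        if np.any(r <= 0):
            raise ValueError("respiration fluxes must be positive")

        # log-linear start: ln R = ln r25 + ((T-25)/10) ln q10
        x = (t - 25.0) / 10.0
        slope, intercept = np.polyfit(x, np.log(r), 1)
        p0 = (float(np.exp(intercept)), float(np.exp(slope)))
        popt, pcov = curve_fit(
            self._model, t, r, p0=p0,
            bounds=([1e-8, 1e-3], [np.inf, np.inf]), maxfev=10000,
        )
        self.r25_, self.q10_ = float(popt[0]), float(popt[1])
        se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 2
        self.std_errors_ = {"r25": float(se[0]), "q10": float(se[1])}
        self.r_squared_ = _r_squared(r, self._model(t, *popt))
        self.n_points_ = int(t.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "r25_")
        return self._model(np.asarray(X, dtype=float).ravel(), self.r25_, self.q10_)

    def result_(self) -> RespTempFit:
        check_is_fitted(self, "r25_")
        return RespTempFit(
            r25=self.r25_, q10=self.q10_, r_squared=self.r_squared_,
            n_points=self.n_points_, std_errors=self.std_errors_,
        )


# ---------------------------------------------------------------------------
# table-level functions


def fit_parabolic(points: pd.DataFrame) -> PhotoTempFit:
    """Fit the parabola to a table of light-mode gas-exchange points.

    Expects columns ``tleaf_C`` and ``anet_umol_m2_s`` (and, if present,
    ``mode`` must be 'light' throughout).  Precondition violations and
    degenerate fits are returned as flagged failure records rather than
    silently dropped.
    """
    if "mode" in points.columns and not (points["mode"] == "light").all():
        raise ValueError("fit_parabolic expects light-mode points only")
    t = points["tleaf_C"].to_numpy(float)
    a = points["anet_umol_m2_s"].to_numpy(float)
    try:
        est = ParabolicTemperatureResponse().fit(t, a)
    except ValueError as exc:
        return PhotoTempFit(
            a_opt=np.nan, t_opt=np.nan, b=np.nan, t80=np.nan,
            r_squared=np.nan, n_points=int(t.size), flag=str(exc),
        )
    return est.result_()


def fit_exponential(points: pd.DataFrame) -> RespTempFit:
    """Fit the Q10 exponential to a table of dark-mode points."""
    if "mode" in points.columns and not (points["mode"] == "dark").all():
        raise ValueError("fit_exponential expects dark-mode points only")
    if "ppfd" in points.columns and (points["ppfd"] > 0).any():
        raise ValueError("dark-mode points must have ppfd == 0")
    t = points["tleaf_C"].to_numpy(float)
    r = points["anet_umol_m2_s"].to_numpy(float)
    try:
        est = ExponentialRespirationResponse().fit(t, r)
    except ValueError as exc:
        return RespTempFit(
            r25=np.nan, q10=np.nan, r_squared=np.nan,
            n_points=int(t.size), flag=str(exc),
        )
    fit = est.result_()
    if fit.q10 <= 1.0:
        fit.flag = "q10 <= 1 (flagged, excluded downstream)"
    return fit


def fit_curves_table(obs: pd.DataFrame,
                     group_cols=("site", "species", "individual", "campaign"),
                     ) -> pd.DataFrame:
    """Fit per-group response curves for a full observation table.

    Light-mode groups get the parabola (a_opt/t_opt/b/t80), dark-mode groups
    the exponential (r25/q10); one output row per group carrying whichever
    set applies, plus fit diagnostics and a ``flag`` column.  Flagged rows are
    retained so downstream stages can count exclusions.
    """
    group_cols = [c for c in group_cols if c in obs.columns]
    rows = []
    for key, grp in obs.groupby([*group_cols, "mode"], sort=True):
        *key_vals, mode = key
        row = dict(zip(group_cols, key_vals))
        if "antecedent_tair_C" in grp.columns:
            row["antecedent_tair_C"] = float(grp["antecedent_tair_C"].iloc[0])
        if mode == "light":
            fit = fit_parabolic(grp)
            row.update(a_opt=fit.a_opt, t_opt=fit.t_opt, b=fit.b, t80=fit.t80,
                       r2=fit.r_squared, n=fit.n_points, flag=fit.flag)
        else:
            fit = fit_exponential(grp)
            row.update(r25=fit.r25, q10=fit.q10,
                       r2=fit.r_squared, n=fit.n_points, flag=fit.flag)
        rows.append(row)
    return pd.DataFrame(rows)
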