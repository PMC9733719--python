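"""Square-root-scale harmonic model of the diurnal pattern and age trend.

The hourly sqrt-scale mean is

    mu0 + beta*day + sum_{i=1..3} (A_i + delta_i*day) * sin(b_i*hour + c_i)

with fixed angular frequencies ``b_i = i*2*pi/24`` (24, 12 and 8-hour
cycles).  Estimation linearizes each wave as
``u*sin(b*t) + v*cos(b*t)`` with ``u = A*cos(c)``, ``v = A*sin(c)``, so the
fixed effects are linear; amplitude and phase are derived afterwards in
canonical form (A >= 0, c in (-pi, pi]) with delta-method standard errors.

Fixed effects are estimated by OLS with cluster-robust (by pen) standard
errors; pen and day-within-pen intercept variances and the within-day AR(1)
coefficient are recovered from the residuals by method of moments.  This is
the documented generalized-least-squares fallback for the full mixed
likelihood: on the balanced hourly lattice the OLS fixed effects are
unbiased and the clustered standard errors account for the dependence.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import WAVE_FREQUENCIES

logger = logging.getLogger(__name__)


def design_columns(n_waves: int = 3) -> list[str]:
    cols = ["intercept", "day"]
    cols += [f"{fn}{i}" for i in range(1, n_waves + 1) for fn in ("sin", "cos")]
    cols += [f"day_{fn}{i}" for i in range(1, n_waves + 1) for fn in ("sin", "cos")]
    return cols


def build_harmonic_design(rows: pd.DataFrame, n_waves: int = 3) -> pd.DataFrame:
    """Design matrix: intercept, day, sin/cos pairs, day x sin/cos pairs.

    ``rows`` must carry ``day`` and ``hour``.  For 3 waves this yields
    2 + 4*3 = 14 columns.
    """
    if n_waves < 1:
        raise ValueError(f"n_waves must be >= 1, got {n_waves}")
    if n_waves > len(WAVE_FREQUENCIES):
        raise ValueError(f"at most {len(WAVE_FREQUENCIES)} waves supported")
    day = rows["day"].to_numpy(dtype=float)
    hour = rows["hour"].to_numpy(dtype=float)
    data = {"intercept": np.ones(len(rows)), "day": day}
    for i in range(1, n_waves + 1):
        b = WAVE_FREQUENCIES[i - 1]
        data[f"sin{i}"] = np.sin(b * hour)
        data[f"cos{i}"] = np.cos(b * hour)
    for i in range(1, n_waves + 1):
        data[f"day_sin{i}"] = day * data[f"sin{i}"]
        data[f"day_cos{i}"] = day * data[f"cos{i}"]
    return pd.DataFrame(data, index=rows.index)[design_columns(n_waves)]


def amplitude_phase(u: float, v: float) -> tuple[float, float]:
    """Canonical (amplitude, phase) of u*sin(bt) + v*cos(bt) = A*sin(bt + c)."""
    a = math.hypot(u, v)
    c = math.atan2(v, u) if a > 0 else 0.0
    return a, c


def phase_coeffs(amplitude: float, phase: float) -> tuple[float, float]:
    """Inverse of :func:`amplitude_phase`."""
    return amplitude * math.cos(phase), amplitude * math.sin(phase)


def canonicalize(amplitude: float, phase: float) -> tuple[float, float]:
    """Map any (A, c) onto A >= 0 with c wrapped into (-pi, pi]."""
    if amplitude < 0:
        amplitude, phase = -amplitude, phase + math.pi
    phase = math.remainder(phase, 2.0 * math.pi)
    if phase <= -math.pi:
        phase += 2.0 * math.pi
    return amplitude, phase


@dataclass
class HarmonicFit:
    """Fitted harmonic model in both raw-coefficient and canonical form."""

    response: str
    n_waves: int
    params: pd.Series                  # raw linearized coefficients
    cov: np.ndarray                    # cluster-robust covariance of params
    mean0: float = 0.0
    trend: float = 0.0
    amplitudes: tuple = ()
    phases: tuple = ()
    amp_trends: tuple = ()
    se: pd.Series | None = None
    amplitude_se: tuple = ()
    phase_se: tuple = ()
    pen_sd: float = 0.0
    day_sd: float = 0.0
    resid_sd: float = 0.0
    rho: float = 0.0
    n_obs: int = 0
    n_pens: int = 0
    day_range: tuple = (1, 1)
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def linear_predictor(self, day, hour) -> np.ndarray:
        rows = pd.DataFrame(
            {"day": np.asarray(day, dtype=float).ravel(), "hour": np.asarray(hour, dtype=float).ravel()}
        )
        X = build_harmonic_design(rows, self.n_waves).to_numpy()
        return X @ self.params.to_numpy()


def _variance_components(df: pd.DataFrame, resid: np.ndarray) -> dict:
    """Method-of-moments pen/day/residual variances and AR(1) coefficient."""
    work = pd.DataFrame(
        {
            "pen": df["pen_id"].to_numpy(),
            "day": df["day"].to_numpy(),
            "hour": df["hour"].to_numpy(),
            "r": resid,
        }
    ).sort_values(["pen", "day", "hour"])
    day_mean = work.groupby(["pen", "day"])["r"].transform("mean")
    pen_mean = work.groupby("pen")["r"].transform("mean")
    e = (work["r"] - day_mean).to_numpy()
    # lag-1 autocorrelation within pen-day hour runs
    same_run = (
        (work["pen"].to_numpy()[1:] == work["pen"].to_numpy()[:-1])
        & (work["day"].to_numpy()[1:] == work["day"].to_numpy()[:-1])
        & (work["hour"].to_numpy()[1:] == work["hour"].to_numpy()[:-1] + 1)
    )
    e0, e1 = e[:-1][same_run], e[1:][same_run]
    denom = math.sqrt(float(e0 @ e0) * float(e1 @ e1))
    rho = float(e0 @ e1) / denom if denom > 0 else 0.0
    # first-order correction for the downward bias induced by demeaning
    # 24-hour runs: E[rho_hat] ~ rho - (1 + 3*rho)/T
    rho = rho + (1.0 + 3.0 * rho) / 24.0
    rho = float(np.clip(rho, -0.99, 0.99))
    n_runs = work.groupby(["pen", "day"]).ngroups
    dof = max(len(work) - n_runs, 1)
    resid_var = float(e @ e) / dof
    # inflation factor of a 24-hour AR(1) mean relative to sigma^2/24
    k = np.arange(1, 24)
    f = 1.0 + 2.0 * float(np.sum((1.0 - k / 24.0) * rho**k))
    day_dev = (day_mean - pen_mean).to_numpy()
    day_cells = work.assign(dm=day_dev).groupby(["pen", "day"])["dm"].first()
    n_days_per_pen = day_cells.groupby("pen").size()
    ss = float((day_cells**2).sum())
    dof_day = max(int((n_days_per_pen - 1).sum()), 1)
    day_var = max(ss / dof_day - resid_var * f / 24.0, 0.0)
    pen_means = work.groupby("pen")["r"].mean()
    n_days_avg = float(n_days_per_pen.mean())
    pen_var = max(
        float(pen_means.var(ddof=1)) - (day_var + resid_var * f / 24.0) / n_days_avg, 0.0
    ) if len(pen_means) > 1 else 0.0
    return {
        "pen_sd": math.sqrt(pen_var),
        "day_sd": math.sqrt(day_var),
        "resid_sd": math.sqrt(resid_var),
        "rho": rho,
    }


def fit_harmonic_mixed(
    pen_hourly: pd.DataFrame,
    response: str = "water",
    n_waves: int = 3,
    estimate_variances: bool = True,
) -> HarmonicFit:
    """Fit the harmonic age-trend model to sqrt-transformed hourly data.

    Requires data spanning at least 2 days and 2 pens.  Rows where the
    response is missing (e.g. cleaned out) are dropped.
    """
    df = pen_hourly.dropna(subset=[response])
    if df["day"].nunique() < 2 or df["pen_id"].nunique() < 2:
        raise ValueError("need data spanning >= 2 days and >= 2 pens")
    if (df[response] < 0).any():
        raise ValueError(f"{response} contains negative values")
    y = np.sqrt(df[response].to_numpy(dtype=float))
    X = build_harmonic_design(df, n_waves)
    if len(df) <= X.shape[1]:
        raise ValueError("fewer observations than parameters")
    model = sm.OLS(y, X)
    try:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": df["pen_id"].to_numpy()})
    except Exception as exc:  # never fail silently
        raise RuntimeError(f"harmonic fit failed: {exc}") from exc
    params = res.params
    cov = np.asarray(res.cov_params())
    amplitudes, phases, amp_trends, amp_se, phase_se = [], [], [], [], []
    names = list(params.index)
    for i in range(1, n_waves + 1):
        iu, iv = names.index(f"sin{i}"), names.index(f"cos{i}")
        u, v = params.iloc[iu], params.iloc[iv]
        a, c = canonicalize(*amplitude_phase(u, v))
        amplitudes.append(a)
        phases.append(c)
        ud, vd = params[f"day_sin{i}"], params[f"day_cos{i}"]
        amp_trends.append((u * ud + v * vd) / a if a > 0 else 0.0)
        sub = cov[np.ix_([iu, iv], [iu, iv])]
        if a > 0:
            ga = np.array([u / a, v / a])
            gc = np.array([-v / a**2, u / a**2])
            amp_se.append(float(np.sqrt(ga @ sub @ ga)))
            phase_se.append(float(np.sqrt(gc @ sub @ gc)))
        else:
            amp_se.append(float("nan"))
            phase_se.append(float("nan"))
    resid = y - res.fittedvalues
    if estimate_variances:
        vc = _variance_components(df, np.asarray(resid))
    else:
        vc = {"pen_sd": 0.0, "day_sd": 0.0, "resid_sd": float(np.std(resid)), "rho": 0.0}
    fit = HarmonicFit(
        response=response,
        n_waves=n_waves,
        params=params,
        cov=cov,
        mean0=float(params["intercept"]),
        trend=float(params["day"]),
        amplitudes=tuple(amplitudes),
        phases=tuple(phases),
        amp_trends=tuple(amp_trends),
        se=res.bse,
        amplitude_se=tuple(amp_se),
        phase_se=tuple(phase_se),
        n_obs=int(len(df)),
        n_pens=int(df["pen_id"].nunique()),
        day_range=(int(df["day"].min()), int(df["day"].max())),
        converged=True,
        diagnostics={"r_squared": float(res.rsquared)},
        **vc,
    )
    logger.info(
        "harmonic fit (%s): n=%d pens=%d mean0=%.4f trend=%.6f rho=%.3f",
        response, fit.n_obs, fit.n_pens, fit.mean0, fit.trend, fit.rho,
    )
    return fit


def predict_diurnal(fit: HarmonicFit, day: float, hours=None) -> np.ndarray:
    """Expected back-transformed use per hour on a given day.

    The sqrt-scale linear predictor is clipped at zero before squaring.  Days
    outside the fitted range are extrapolated with a warning.
    """
    if hours is None:
        hours = np.arange(24)
    hours = np.asarray(hours)
    lo, hi = fit.day_range
    if day < lo or day > hi:
        warnings.warn(
            f"day {day} outside fitted range [{lo}, {hi}]; extrapolating", stacklevel=2
        )
    lin = fit.linear_predictor(np.full(hours.shape, float(day)), hours)
    return np.clip(lin, 0.0, None) ** 2


def daily_total(fit: HarmonicFit, day: float, variance_correction: bool = False) -> float:
    """Per-pig daily use: the 24-hour sum of the back-transformed curve.

    With ``variance_correction`` the pen, day and residual variances are added
    to each hour's squared mean (E[z^2] = m^2 + sigma^2); off by default.
    """
    total = float(np.sum(predict_diurnal(fit, day)))
    if variance_correction:
        total += 24.0 * (fit.pen_sd**2 + fit.day_sd**2 + fit.resid_sd**2)
    return total
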