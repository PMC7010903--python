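"""Time-activity kinetics: uptake curves, retention, and cumulated activity.

A gamma-counter experiment yields, per added activity, the fractions of
activity in three compartments — medium (unbound), membrane-bound, and
internalized — at 15-minute resolution during a 4-h uptake and daily over a
6-day follow-up, all decay-corrected.  This module fits the standard
empirical curve forms (linear membrane binding, exponential-association
internalization, exponential daily retention), interpolates fractions across
added activities by inverse-distance weighting, and converts fractions into
cumulated activities (time-integrated activity, Bq s) per interval:

    A~ = f * A0 * (exp(-lambda_p T1) - exp(-lambda_p T2)) / lambda_p

with times in hours converted to seconds and lambda_p the physical decay
constant of Lu-177 (half-life 6.647 d) unless overridden.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .decay import LU177_LAMBDA_PER_H

__all__ = [
    "FractionTimeSeries",
    "TimeActivityModel",
    "CumulatedActivities",
    "fit_uptake_curves",
    "fit_daily_retention",
    "cumulated_activity",
    "idw_extrapolate",
    "decay_correct",
]

MEDIUM = "medium"
MEMBRANE = "membrane"
INTERNALIZED = "internalized"
COMPARTMENTS = (MEDIUM, MEMBRANE, INTERNALIZED)

SECONDS_PER_HOUR = 3600.0


class KineticsError(ValueError):
    pass


@dataclass
class FractionTimeSeries:
    """Decay-corrected activity fractions per compartment over time.

    ``fractions`` maps compartment name -> array aligned with ``times_h``;
    ``sds`` optionally carries replicate standard deviations.  ``cell_counts``
    maps day (1-based) -> cells per well.
    """

    added_activity_mbq_ml: float
    times_h: np.ndarray
    fractions: dict[str, np.ndarray]
    sds: dict[str, np.ndarray] = field(default_factory=dict)
    cell_counts: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise KineticsError("timepoints must be strictly increasing")
        total = np.zeros_like(self.times_h)
        for name in self.fractions:
            arr = np.asarray(self.fractions[name], dtype=float)
            if arr.shape != self.times_h.shape:
                raise KineticsError(f"fraction array shape mismatch for {name!r}")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise KineticsError(f"fractions for {name!r} must be finite and >= 0")
            self.fractions[name] = arr
            total += arr
        if np.any(total > 1.0 + 0.5):
            raise KineticsError("compartment fractions sum above 1 beyond tolerance")

    def uptake_mask(self, t_end_h: float = 4.0) -> np.ndarray:
        return self.times_h <= t_end_h + 1e-9


@dataclass
class TimeActivityModel:
    """Fitted empirical uptake/retention curves for one added activity.

    Membrane binding is linear in incubation time, internalization follows an
    exponential association A_plat (1 - exp(-k t)), and the daily per-cell
    retention declines exponentially with the effective rate lambda_eff.
    """

    membrane_slope: float
    membrane_intercept: float
    internalized_plateau: float
    internalized_rate: float
    r2: dict[str, float]
    lambda_eff_per_h: float | None = None
    lambda_eff_sd: float | None = None
    lambda_p_per_h: float = LU177_LAMBDA_PER_H
    flags: list[str] = field(default_factory=list)

    def membrane(self, t_h: np.ndarray) -> np.ndarray:
        return self.membrane_intercept + self.membrane_slope * np.asarray(t_h, float)

    def internalized(self, t_h: np.ndarray) -> np.ndarray:
        return self.internalized_plateau * (
            1.0 - np.exp(-self.internalized_rate * np.asarray(t_h, float))
        )


@dataclass
class CumulatedActivities:
    """Cumulated activities (Bq s) per interval and compartment.

    ``intervals`` are (label, T1_h, T2_h); the table holds one row per
    interval with columns A_M, A_CS, A_C (per cell where normalised).
    """

    table: pd.DataFrame  # index: interval label; columns: medium/membrane/internalized

    def total(self, compartment: str) -> float:
        return float(self.table[compartment].sum())


def _r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_uptake_curves(
    series: FractionTimeSeries,
    r2_flag_threshold: float = 0.95,
    membrane_model: str = "linear",
) -> TimeActivityModel:
    """Least-squares fits of the 0-4 h uptake curves.

    ``membrane_model`` is ``"linear"`` (default: linear through 4 h) or
    ``"saturating"`` (linear rise to 15 min, constant after), the two readings
    of fast membrane saturation.  Curves with R^2 below the threshold are
    flagged, not rejected.
    """
    mask = series.uptake_mask()
    t = series.times_h[mask]
    if t.size < 4:
        raise KineticsError("need at least 4 uptake timepoints in 0-4 h")
    flags: list[str] = []
    r2: dict[str, float] = {}

    y_mem = series.fractions[MEMBRANE][mask]
    if not np.all(np.isfinite(y_mem)):
        raise KineticsError("non-finite membrane fractions")
    if membrane_model == "linear":
        slope, intercept = np.polyfit(t, y_mem, 1)
        pred = intercept + slope * t
    elif membrane_model == "saturating":
        level = float(np.mean(y_mem[t >= 0.25])) if np.any(t >= 0.25) else float(y_mem[-1])
        slope, intercept = 0.0, level
        pred = np.where(t < 0.25, level * t / 0.25, level)
    else:
        raise KineticsError(f"unknown membrane model {membrane_model!r}")
    r2[MEMBRANE] = _r_squared(y_mem, pred)

    y_int = series.fractions[INTERNALIZED][mask]

    def assoc(tt, plateau, k):
        return plateau * (1.0 - np.exp(-k * tt))

    p0 = (max(float(y_int[-1]), 1e-9), 1.0)
    try:
        popt, _ = curve_fit(
            assoc, t, y_int, p0=p0, bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise KineticsError(f"internalized-curve fit failed to converge: {exc}") from exc
    r2[INTERNALIZED] = _r_squared(y_int, assoc(t, *popt))

    for name in (MEMBRANE, INTERNALIZED):
        if r2[name] < r2_flag_threshold:
            flags.append(f"{name} fit R2 {r2[name]:.3f} < {r2_flag_threshold}")
    return TimeActivityModel(
        membrane_slope=float(slope),
        membrane_intercept=float(intercept),
        internalized_plateau=float(popt[0]),
        internalized_rate=float(popt[1]),
        r2=r2,
        flags=flags,
    )


def fit_daily_retention(
    times_h: np.ndarray,
    per_cell_activity: np.ndarray,
    r2_flag_threshold: float = 0.94,
) -> tuple[float, float, float, list[str]]:
    """Exponential fit of decay-corrected per-cell activity over the follow-up.

    Returns (lambda_eff per h, its SD, R^2, flags).  An increasing series is
    fitted anyway with a warning flag (lambda_eff may come out ~0 or negative
    within its SD).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(per_cell_activity, dtype=float)
    if t.size < 3:
        raise KineticsError("need at least 3 daily points")
    flags: list[str] = []
    if y[-1] > y[0]:
        flags.append("activity series increases; retention fit is extrapolatory")

    if np.all(y > 0):
        # log-linear regression: exact for multiplicative (lognormal) noise,
        # with an honest slope covariance (combine with a t quantile at
        # n - 2 degrees of freedom for interval coverage)
        coef, cov = np.polyfit(t, np.log(y), 1, cov="unscaled" if t.size <= 2 else True)
        lam = float(-coef[0])
        lam_sd = float(np.sqrt(cov[0, 0]))
        pred = np.exp(np.polyval(coef, t))
    else:

        def model(tt, a0, lam_):
            return a0 * np.exp(-lam_ * tt)

        popt, pcov = curve_fit(model, t, y, p0=(max(float(y[0]), 1e-30), 0.02),
                               maxfev=20000)
        lam = float(popt[1])
        lam_sd = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
        pred = model(t, *popt)
    r2 = _r_squared(y, pred)
    if r2 < r2_flag_threshold:
        flags.append(f"retention fit R2 {r2:.3f} < {r2_flag_threshold}")
    return lam, lam_sd, r2, flags


def cumulated_activity(
    fraction: float,
    a0_bq: float,
    t1_h: float,
    t2_h: float,
    lambda_p_per_h: float = LU177_LAMBDA_PER_H,
) -> float:
    """Cumulated activity (Bq s) of a compartment over [T1, T2] hours.

    Closed form of f * integral of A0 exp(-lambda_p t); the lambda_p <= 0
    branch returns the no-decay limit f * A0 * (T2 - T1).
    """
    if not t2_h > t1_h or t1_h < 0:
        raise KineticsError("need T2 > T1 >= 0")
    if fraction < 0:
        raise KineticsError("fraction must be >= 0")
    if lambda_p_per_h <= 0:
        hours = t2_h - t1_h
    else:
        lam = lambda_p_per_h
        hours = (np.exp(-lam * t1_h) - np.exp(-lam * t2_h)) / lam
    return float(fraction * a0_bq * hours * SECONDS_PER_HOUR)


def decay_correct(
    measured_activity: float | np.ndarray,
    elapsed_h: float | np.ndarray,
    lambda_p_per_h: float = LU177_LAMBDA_PER_H,
) -> float | np.ndarray:
    """Back-correct a measured activity to the reference time."""
    if np.any(np.asarray(elapsed_h) < 0):
        raise KineticsError("elapsed time must be >= 0")
    return measured_activity * np.exp(lambda_p_per_h * np.asarray(elapsed_h, float))


def build_cumulated_table(
    series: FractionTimeSeries,
    model: TimeActivityModel,
    a0_bq: float,
    lambda_p_per_h: float = LU177_LAMBDA_PER_H,
    fine_dt_h: float = 0.01,
) -> pd.DataFrame:
    """Cumulated activities (Bq s) per interval and kinetics channel.

    The 4-h uptake interval integrates the fitted time-activity curves
    (times the physical-decay factor) on a fine trapezoidal grid; follow-up
    days use the closed form with the fraction measured on that day held
    constant over the interval.  Cellular channels (membrane, internalized)
    are normalised per cell by the measured cell count of the day
    (exponentially interpolated between measured days); the medium channel
    stays per well.

    Rows: 'uptake', 'day1' (4-24 h) ... 'day6'.
    """
    counts = dict(series.cell_counts)
    if 0 not in counts:
        raise KineticsError("cell_counts must include day 0 (cells at seeding)")

    def count_at(day: int) -> float:
        if day in counts:
            return counts[day]
        known = sorted(counts)
        lo = max(d for d in known if d < day)
        hi_candidates = [d for d in known if d > day]
        if not hi_candidates:  # extrapolate from the last growth rate
            lo2, lo1 = known[-2], known[-1]
            rate = np.log(counts[lo1] / counts[lo2]) / (lo1 - lo2)
            return counts[lo1] * np.exp(rate * (day - lo1))
        hi = min(hi_candidates)
        w = (day - lo) / (hi - lo)
        return float(np.exp((1 - w) * np.log(counts[lo]) + w * np.log(counts[hi])))

    # uptake: trapezoidal integral of the fitted curves
    tg = np.arange(0.0, 4.0 + fine_dt_h / 2, fine_dt_h)
    decay = np.exp(-lambda_p_per_h * tg)
    f_cs = np.clip(model.membrane(tg), 0.0, None)
    f_c = np.clip(model.internalized(tg), 0.0, None)
    f_m = np.clip(1.0 - f_cs - f_c, 0.0, None)
    rows = {}
    n0 = counts[0]
    rows["uptake"] = {
        MEDIUM: np.trapezoid(a0_bq * f_m * decay, tg) * SECONDS_PER_HOUR,
        MEMBRANE: np.trapezoid(a0_bq * f_cs * decay, tg) * SECONDS_PER_HOUR / n0,
        INTERNALIZED: np.trapezoid(a0_bq * f_c * decay, tg) * SECONDS_PER_HOUR / n0,
    }

    daily_t = series.times_h[~series.uptake_mask()]
    for day in range(1, 7):
        t_meas = 24.0 * day
        idx = np.argmin(np.abs(daily_t - t_meas)) if daily_t.size else None
        if idx is None or abs(daily_t[idx] - t_meas) > 6.0:
            raise KineticsError(f"no measurement near day {day}")
        t_sel = daily_t[idx]
        sel = np.nonzero(series.times_h == t_sel)[0][0]
        t1, t2 = (4.0, 24.0) if day == 1 else (24.0 * (day - 1), 24.0 * day)
        n_cells = count_at(day)
        row = {}
        for channel, per_cell in ((MEDIUM, False), (MEMBRANE, True), (INTERNALIZED, True)):
            f = float(series.fractions[channel][sel])
            a = cumulated_activity(f, a0_bq, t1, t2, lambda_p_per_h)
            row[channel] = a / n_cells if per_cell else a
        rows[f"day{day}"] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def idw_extrapolate(
    grid: pd.DataFrame,
    activity_mbq_ml: float,
    time_h: float,
    compartment: str,
    power: float = 2.0,
) -> float:
    """Inverse-distance-weighted fraction at (added activity, time).

    ``grid`` needs columns ``added_activity_MBq_per_ml``, ``time_h``,
    ``compartment``, ``fraction``.  Distances are Euclidean over
    (log10 activity, time), each axis normalised by its grid span, within the
    queried compartment; weights are d^-power and a zero distance returns the
    node value exactly.  Queries outside the grid's activity span are
    extrapolations and are flagged via a returned-value warning attribute on
    the module logger — the value is still returned.
    """
    if power <= 0:
        raise KineticsError("IDW power must be > 0")
    sub = grid[grid["compartment"] == compartment]
    if sub.empty:
        raise KineticsError(f"no grid nodes for compartment {compartment!r}")
    log_a = np.log10(sub["added_activity_MBq_per_ml"].to_numpy(dtype=float))
    t = sub["time_h"].to_numpy(dtype=float)
    v = sub["fraction"].to_numpy(dtype=float)
    qa = np.log10(activity_mbq_ml)
    span_a = np.ptp(log_a) or 1.0
    span_t = np.ptp(t) or 1.0
    d = np.hypot((log_a - qa) / span_a, (t - time_h) / span_t)
    exact = d < 1e-12
    if exact.any():
        return float(v[exact][0])
    if qa < log_a.min() - 1e-12 or qa > log_a.max() + 1e-12:
        import warnings

        warnings.warn(
            "IDW query outside the added-activity span: extrapolating",
            stacklevel=2,
        )
    w = d ** (-power)
    return float(np.sum(w * v) / np.sum(w))
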