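"""Growth-curve kinetics and bacterial growth efficiency (BGE).

Prokaryotic abundance (PA, cells L⁻¹) in each incubation bottle is fitted
with a logistic model

    N(t) = K / (1 + ((K − N0)/N0) · exp(−r t)),

from which the half-capacity time t_mid = ln((K − N0)/N0)/r delimits the
stationary phase at t_stationary = 2·t_mid.  The specific growth rate μ is
the OLS slope of ln(PA) against time over the exponential window, whose
start is the time of minimum observed abundance before t_mid (so an initial
die-off, as in the deep-inoculum treatment, is excluded) and whose end is
t_stationary.  BGE is the ratio of the time-integrated biomass-carbon
increase above its start-of-window value to the time-integrated DOC
drawdown below its start-of-window value over the same interval, with
biomass carbon from a 20 fg C cell⁻¹ conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GrowthFit",
    "BgeResult",
    "FitError",
    "NoGrowthError",
    "fit_logistic",
    "exponential_window",
    "specific_growth_rate",
    "interpolate_at",
    "integrate_excess",
    "bacterial_carbon",
    "compute_bge",
    "window_rate",
    "analyze_growth",
    "growth_table",
]

CARBON_MOLAR_MASS = 12.011  # g mol⁻¹


class FitError(RuntimeError):
    """Logistic fit failed to converge."""


class NoGrowthError(FitError):
    """The series carries no growth signal (constant or decreasing)."""


@dataclass
class GrowthFit:
    K: float            # carrying capacity, cells L⁻¹
    r: float            # intrinsic logistic rate, d⁻¹
    N0: float           # abundance at t = 0 on the fitted curve, cells L⁻¹
    t_mid: float        # time of half carrying capacity, d
    t_stationary: float  # 2 · t_mid, d
    rss: float
    window: tuple[float, float] | None = None  # exponential phase [t_start, t_end]
    mu: float | None = None                    # ln-slope over window, d⁻¹

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        return logistic(t, self.K, self.r, self.N0)


@dataclass
class BgeResult:
    integral_bc: float       # µmol C·d L⁻¹ above the T0 biomass carbon
    integral_doc: float      # µmol C·d L⁻¹ below the T0 DOC
    bge: float               # fraction; NaN when flagged
    fg_per_cell: float
    window: tuple[float, float]
    flag: str | None = None  # "no net DOC removal" when ∫DOC ≤ 0

    @property
    def bge_percent(self) -> float:
        return 100.0 * self.bge


def logistic(t, K, r, N0):
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def fit_logistic(times, abundances) -> GrowthFit:
    """Least-squares logistic fit with deterministic initialisation.

    Residuals are taken on the log-abundance scale, the maximum-likelihood
    choice for the multiplicative (lognormal) measurement error typical of
    cell counts; it also conditions the fit far better for slow-growth
    series, where linear-scale residuals leave the capacity nearly
    unidentified.  Initialisation: K from the maximum observation, N0 from
    the first, r from the log-slope of the first three points; K is
    bounded to (max obs, 10·max obs] so the capacity always exceeds the
    data.  The reported ``rss`` is on the abundance scale.
    """
    t = np.asarray(times, float)
    y = np.asarray(abundances, float)
    if len(t) < 5:
        raise FitError(f"need ≥5 observations, got {len(t)}")
    if np.any(y <= 0):
        raise FitError("abundances must be > 0")
    ymax = float(y.max())
    if ymax <= y[0] * (1.0 + 1e-12):
        raise NoGrowthError("no growth signal: series never exceeds its initial value")

    # scale to O(1) for conditioning; parameters are (K, r, N0)/ymax units
    ys = y / ymax
    r0 = stats.linregress(t[:3], np.log(y[:3])).slope
    if not np.isfinite(r0) or r0 <= 0:
        r0 = 0.1
    x0 = np.array([1.05, min(max(r0, 1e-3), 19.0), max(ys[0], 1e-6)])
    lo = np.array([1.0 + 1e-9, 1e-6, 1e-9])
    hi = np.array([10.0, 20.0, 1.0])
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)

    log_ys = np.log(ys)

    def resid(p):
        K, r, N0 = p
        return np.log(logistic(t, K, r, N0)) - log_ys

    sol = optimize.least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError(f"logistic fit did not converge from x0={x0.tolist()}: {sol.message}")
    K, r, N0 = sol.x
    K, N0 = K * ymax, N0 * ymax
    if K <= N0:
        raise FitError("fitted capacity does not exceed fitted N0")
    t_mid = math.log((K - N0) / N0) / r
    return GrowthFit(
        K=K, r=r, N0=N0, t_mid=t_mid, t_stationary=2.0 * t_mid,
        rss=float(np.sum((logistic(t, K, r, N0) - y) ** 2)),
    )


def exponential_window(times, abundances, fit: GrowthFit, min_points: int = 3):
    """Delimit the exponential phase: [time of pre-t_mid minimum, t_stationary].

    Starting at the observed minimum before t_mid accommodates an initial
    die-off; for monotonically rising series the window starts at the first
    timepoint.
    """
    t = np.asarray(times, float)
    y = np.asarray(abundances, float)
    pre = t <= fit.t_mid
    if pre.any():
        t_start = float(t[pre][np.argmin(y[pre])])
    else:
        t_start = float(t[0])
    t_end = float(fit.t_stationary)
    n_in = int(np.sum((t >= t_start) & (t <= t_end)))
    if n_in < min_points:
        raise FitError(
            f"only {n_in} observations in window [{t_start}, {t_end}]; "
            "supply a manual window override"
        )
    return (t_start, t_end)


def specific_growth_rate(times, values, window) -> float:
    """μ: OLS slope of ln(value) vs time restricted to the window, d⁻¹."""
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    m = (t >= window[0]) & (t <= window[1])
    if m.sum() < 2:
        raise ValueError("need ≥2 points inside the window")
    if np.any(y[m] <= 0):
        raise ValueError("nonpositive abundance inside window; cannot take log")
    return float(stats.linregress(t[m], np.log(y[m])).slope)


def interpolate_at(times, values, t: float) -> float:
    """Linear interpolation between bracketing observations; exact at knots."""
    x = np.asarray(times, float)
    y = np.asarray(values, float)
    if t < x[0] or t > x[-1]:
        raise ValueError(f"t={t} outside observed range [{x[0]}, {x[-1]}]")
    return float(np.interp(t, x, y))


def integrate_excess(times, values, window, baseline: float, sign: str = "above",
                     normalize: bool = False) -> float:
    """Trapezoidal integral of the excess relative to a baseline.

    sign="above" integrates (value − baseline); "below" integrates
    (baseline − value).  Window endpoints not coinciding with samples are
    obtained by linear interpolation.  ``normalize`` divides by the window
    length, giving a time-normalised mean excess.
    """
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValueError(f"empty window [{t0}, {t1}]")
    x = np.asarray(times, float)
    y = np.asarray(values, float)
    inside = (x > t0) & (x < t1)
    xs = np.concatenate(([t0], x[inside], [t1]))
    ys = np.concatenate(([interpolate_at(x, y, t0)], y[inside], [interpolate_at(x, y, t1)]))
    if sign == "above":
        excess = ys - baseline
    elif sign == "below":
        excess = baseline - ys
    else:
        raise ValueError("sign must be 'above' or 'below'")
    total = float(np.trapezoid(excess, xs))
    return total / (t1 - t0) if normalize else total


def bacterial_carbon(abundance, fg_per_cell: float = 20.0,
                     molar_mass: float = CARBON_MOLAR_MASS):
    """Cells L⁻¹ → µmol C L⁻¹ via a per-cell carbon content (default 20 fg)."""
    a = np.asarray(abundance, float)
    if np.any(a < 0):
        raise ValueError("abundance must be ≥ 0")
    out = a * fg_per_cell * 1e-15 / molar_mass * 1e6
    return float(out) if np.isscalar(abundance) else out


def compute_bge(pa_times, pa_values, doc_times, doc_values, fit: GrowthFit,
                fg_per_cell: float = 20.0, t0: float | None = None) -> BgeResult:
    """Bacterial growth efficiency over [T0, t_stationary].

    ∫BC is the trapezoidal integral of biomass carbon above its T0 value,
    ∫DOC the integral of DOC below its T0 value; BGE = ∫BC/∫DOC.  The ratio
    is invariant to adding a constant to DOC and to the time-normalisation
    shared by numerator and denominator.
    """
    if t0 is None:
        t0 = fit.window[0] if fit.window else float(np.asarray(pa_times, float)[0])
    t1 = fit.t_stationary
    bc = bacterial_carbon(np.asarray(pa_values, float), fg_per_cell)
    bc0 = interpolate_at(pa_times, bc, t0)
    doc0 = interpolate_at(doc_times, doc_values, t0)
    integral_bc = integrate_excess(pa_times, bc, (t0, t1), bc0, "above")
    integral_doc = integrate_excess(doc_times, doc_values, (t0, t1), doc0, "below")
    if integral_doc <= 0:
        return BgeResult(integral_bc, integral_doc, float("nan"), fg_per_cell,
                         (t0, t1), flag="no net DOC removal")
    return BgeResult(integral_bc, integral_doc, integral_bc / integral_doc,
                     fg_per_cell, (t0, t1))


def window_rate(times, values, t0: float, t1: float) -> float:
    """OLS slope of value vs time on [t0, t1] (units d⁻¹, sign preserved)."""
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    m = (t >= t0) & (t <= t1)
    if m.sum() < 2:
        raise ValueError(f"need ≥2 points in [{t0}, {t1}], got {int(m.sum())}")
    return float(stats.linregress(t[m], y[m]).slope)


def analyze_growth(times, abundances, min_window_points: int = 3) -> GrowthFit:
    """Full growth analysis of one bottle: fit, window, μ.

    Two-pass fit: if the first fit's pre-t_mid abundance minimum falls
    after the first timepoint (initial die-off), the logistic is refitted
    on the post-minimum segment, where the model is valid, before the
    window and μ are computed on the original time axis.
    """
    t = np.asarray(times, float)
    y = np.asarray(abundances, float)
    fit = fit_logistic(t, y)
    pre = t <= fit.t_mid
    t_min = float(t[pre][np.argmin(y[pre])]) if pre.any() else float(t[0])
    if t_min > t[0]:
        seg = t >= t_min
        if seg.sum() >= 5:
            fit = fit_logistic(t[seg], y[seg])
    window = exponential_window(t, y, fit, min_points=min_window_points)
    mu = specific_growth_rate(t, y, window)
    return replace(fit, window=window, mu=mu)


def growth_table(series, analyte: str = "PA", fg_per_cell: float = 20.0,
                 doc_analyte: str = "DOC") -> pd.DataFrame:
    """Per-(treatment, bottle) growth and BGE summary for an IncubationSeries.

    A bottle whose fit degenerates (no growth signal, or too few points in
    the delimited window) yields a diagnostic row with ``fit_error`` set
    instead of aborting the whole table.
    """
    rows = []
    for trt in series.treatments:
        for bottle in series.bottles(trt):
            t, y = series.series(trt, bottle, analyte)
            if len(t) == 0:
                continue
            try:
                fit = analyze_growth(t, y)
            except FitError as exc:
                rows.append({"treatment": trt, "bottle": bottle,
                             "fit_error": str(exc)})
                continue
            row = {
                "treatment": trt, "bottle": bottle,
                "K": fit.K, "r": fit.r, "N0": fit.N0,
                "t_mid": fit.t_mid, "t_stationary": fit.t_stationary,
                "window_start": fit.window[0], "window_end": fit.window[1],
                "mu": fit.mu, "rss": fit.rss,
                "exp_duration": fit.window[1] - fit.window[0],
            }
            td, yd = series.series(trt, bottle, doc_analyte)
            # if QC removed early observations, start the BGE window at the
            # first timepoint both series cover (flagged below)
            t0 = max(fit.window[0], float(td[0]), float(t[0])) if len(td) else None
            if t0 is not None and t0 < fit.t_stationary and td[-1] >= fit.t_stationary:
                bge = compute_bge(t, y, td, yd, fit, fg_per_cell, t0=t0)
                flag = bge.flag or ""
                if t0 > fit.window[0]:
                    flag = (flag + "; " if flag else "") + "window truncated at first valid observation"
                row.update({
                    "integral_bc": bge.integral_bc,
                    "integral_doc": bge.integral_doc,
                    "bge": bge.bge, "bge_percent": bge.bge_percent,
                    "bge_flag": flag,
                })
            rows.append(row)
    return pd.DataFrame(rows)
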