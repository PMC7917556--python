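"""Patch-clamp derived quantities.

Whole-cell Ca2+ charge (Q_Ca) from the leak-subtracted current, membrane
capacitance jumps (dC_m) around a depolarization, readily-releasable-pool
(RRP) fits of cumulative release versus stimulus duration, and the
synaptic-vesicle unit conversions (40 aF per vesicle, 12 active zones per
cell, 0.23 a.u. of iGluSnFR-AUC per vesicle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, UnitError, WindowError

AF_PER_SV = 40.0          # capacitance contributed by one vesicle (aF)
N_AZ = 12                 # active zones per apical inner hair cell
AU_PER_SV = 0.23          # iGluSnFR-AUC per vesicle (a.u.)


def qca(time_s: np.ndarray, current_pA: np.ndarray,
        stim_window_s: tuple[float, float], leak_pA=0.0) -> float:
    """Ca2+ charge: time integral of the leak-subtracted current (pC).

    Trapezoidal integral of (I − leak) over ``stim_window_s``; the sign is
    preserved (inward current gives negative charge).  pA x s = pC.
    """
    t = np.asarray(time_s, dtype=float)
    i = np.asarray(current_pA, dtype=float)
    t0, t1 = stim_window_s
    if t1 <= t0:
        raise WindowError(f"empty stim window {stim_window_s}")
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    if t0 < t[0] - dt / 2 or t1 > t[-1] + dt / 2:
        raise WindowError(f"stim window {stim_window_s} outside trace")
    # snap the window to the nearest samples so float jitter in the time
    # base cannot drop an edge sample
    i0 = int(np.argmin(np.abs(t - t0)))
    i1 = int(np.argmin(np.abs(t - t1)))
    sel = slice(i0, i1 + 1)
    leak = np.asarray(leak_pA, dtype=float)
    leak_sel = leak[sel] if leak.ndim else leak
    return float(np.trapezoid(i[sel] - leak_sel, t[sel]))


def delta_cm(time_s: np.ndarray, cm_fF: np.ndarray,
             stim_window_s: tuple[float, float], pre_s: float = 0.4,
             skip_s: float = 0.1, post_s: float = 0.4) -> float:
    """Capacitance jump around a depolarization (fF).

    Mean C_m over [end + skip, end + skip + post] minus mean over
    [start − pre, start]: the average 400 ms before versus after the step,
    skipping the first 100 ms after it.
    """
    t = np.asarray(time_s, dtype=float)
    cm = np.asarray(cm_fF, dtype=float)
    t0, t1 = stim_window_s
    if t0 - pre_s < t[0] or t1 + skip_s + post_s > t[-1]:
        raise WindowError("insufficient margin for the dC_m windows")
    before = cm[(t >= t0 - pre_s) & (t < t0)]
    after = cm[(t >= t1 + skip_s) & (t < t1 + skip_s + post_s)]
    return float(after.mean() - before.mean())


@dataclass
class PoolFit:
    """RRP-depletion fit ``RRP (1 − e^(−t/τ)) + slope·t``."""

    rrp_size: float        # response units (fF or a.u.)
    tau_ms: float
    slope_per_ms: float
    r_squared: float
    converged: bool = True

    @property
    def slope_per_s(self) -> float:
        return self.slope_per_ms * 1000.0


def _pool_model(t_ms, rrp, tau_ms, slope):
    return rrp * (1.0 - np.exp(-t_ms / tau_ms)) + slope * t_ms


def fit_pool(durations_ms, responses, fit_slope: bool = True) -> PoolFit:
    """Fit cumulative release versus stimulus duration.

    The exponential component saturates with time constant τ (RRP
    depletion); the linear component is sustained release.  Needs at least
    four distinct durations.  ``fit_slope=False`` constrains the sustained
    component to zero (purely saturating data), which sharpens the τ
    estimate when the three-parameter model is poorly identified.
    """
    t = np.asarray(durations_ms, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(t)) < 4:
        raise FitError("need >= 4 distinct stimulus durations")
    slope0 = max(y[-1] / t[-1], 1e-9) if t[-1] > 0 else 1e-9
    rrp0 = max(float(y.max() - slope0 * t.max() * 0.5), 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fit_slope:
                popt, _ = curve_fit(
                    _pool_model, t, y, p0=(rrp0, 10.0, slope0),
                    bounds=([0, 1e-3, 0], [np.inf, 1e5, np.inf]),
                    maxfev=20_000)
            else:
                popt, _ = curve_fit(
                    lambda t, rrp, tau: _pool_model(t, rrp, tau, 0.0),
                    t, y, p0=(max(float(y.max()), 1e-6), 10.0),
                    bounds=([0, 1e-3], [np.inf, 1e5]), maxfev=20_000)
                popt = (*popt, 0.0)
    except (RuntimeError, ValueError):
        return PoolFit(rrp_size=np.nan, tau_ms=np.nan, slope_per_ms=np.nan,
                       r_squared=np.nan, converged=False)
    resid = y - _pool_model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return PoolFit(rrp_size=float(popt[0]), tau_ms=float(popt[1]),
                   slope_per_ms=float(popt[2]), r_squared=r2)


def sv_convert(value: float, units: str, af_per_sv: float = AF_PER_SV,
               n_az: int = N_AZ, au_per_sv: float = AU_PER_SV) -> float:
    """Convert measured release into synaptic-vesicle units.

    * ``"fF_per_s"`` → vesicles/s per AZ: (value·1000 / aF-per-SV) / n_AZ
      (whole-cell capacitance rate shared across the cell's AZs);
    * ``"au_per_s"`` → vesicles/s per AZ: value / a.u.-per-SV (iGluSnFR is
      already a single-AZ measurement);
    * ``"au"`` → vesicle count: value / a.u.-per-SV.

    Full precision is returned; round at reporting time.
    """
    if af_per_sv <= 0 or n_az <= 0 or au_per_sv <= 0:
        raise ValueError("conversion constants must be positive")
    if units == "fF_per_s":
        return (value * 1000.0 / af_per_sv) / n_az
    if units == "au_per_s":
        return value / au_per_sv
    if units == "au":
        return value / au_per_sv
    raise UnitError(f"unknown units {units!r}")
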