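"""Fluorescence–voltage fits and the Ca2+ cooperativity of release.

Per synapse, two transfer curves are fitted:

* glutamate release versus step potential — a Boltzmann on the normalized
  iGluSnFR-AUC, ``AUC(V) = 1 / (1 + exp((V_half − V)/k))``;
* synaptic Ca2+ influx versus ramp potential — a driving-force-modified
  Boltzmann on the Rhod-FF dF/F0,
  ``F(V) = F0 + g_max (V − V_r) / (1 + exp((V_half − V)/k))`` with the
  reversal potential fixed at +47.6 mV.

Descriptors come from closed forms of the Boltzmann: activation threshold
V10 = V_half − k·ln 9 and 10–90% dynamic range k·ln 81.  The apparent Ca2+
cooperativity m is the exponent of a power fit of the release curve against
the Ca2+ curve over −57…−17 mV, restricted to release below 25% of maximum.
Fits with R² <= 0.7 are flagged excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError
from .synthgen import V_R_MV

log = logging.getLogger(__name__)

LN9 = float(np.log(9.0))
LN81 = float(np.log(81.0))
R2_GATE = 0.7
COOP_GRID_MV = (-57.0, -17.0)
COOP_CUTOFF = 0.25


def _r2(y, yhat):
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def _boltzmann(V, v_half, k):
    return 1.0 / (1.0 + np.exp((v_half - V) / k))


@dataclass
class BoltzmannFit:
    """Normalized Boltzmann fit with its closed-form descriptors."""

    v_half_mV: float
    k_mV: float
    amplitude: float
    r_squared: float
    n_points: int
    excluded: bool = False
    converged: bool = True

    @property
    def v10_mV(self) -> float:
        """Activation threshold: voltage of 10% activation."""
        return self.v_half_mV - self.k_mV * LN9

    @property
    def v90_mV(self) -> float:
        return self.v_half_mV + self.k_mV * LN9

    @property
    def dynamic_range_mV(self) -> float:
        """10–90% activation span, k·ln 81."""
        return self.k_mV * LN81

    def __call__(self, V):
        return self.amplitude * _boltzmann(np.asarray(V, float),
                                           self.v_half_mV, self.k_mV)


def fit_release_boltzmann(V_mV, responses, normalize: bool = True,
                          r2_gate: float = R2_GATE) -> BoltzmannFit:
    """Boltzmann fit of release (iGluSnFR-AUC) versus step potential.

    Responses are normalized to their maximum before fitting (amplitude
    fixed at 1), matching how normalized release curves are reported.
    Initialization: V_half at the half-maximum crossing, k = 5 mV.
    """
    V = np.asarray(V_mV, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(V) < 5:
        raise FitError("need >= 5 voltage points for a Boltzmann fit")
    ymax = y.max()
    if normalize:
        if ymax <= 0:
            return BoltzmannFit(np.nan, np.nan, np.nan, np.nan, len(V),
                                excluded=True, converged=False)
        y = y / ymax
    order = np.argsort(V)
    v_sorted, y_sorted = V[order], y[order]
    above = np.flatnonzero(y_sorted >= 0.5 * y_sorted.max())
    v_half0 = float(v_sorted[above[0]]) if len(above) else float(np.median(V))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_boltzmann, V, y, p0=(v_half0, 5.0),
                                bounds=([-120, 0.1], [60, 60]), maxfev=20_000)
    except (RuntimeError, ValueError):
        return BoltzmannFit(np.nan, np.nan, np.nan, np.nan, len(V),
                            excluded=True, converged=False)
    r2 = _r2(y, _boltzmann(V, *popt))
    return BoltzmannFit(v_half_mV=float(popt[0]), k_mV=float(popt[1]),
                        amplitude=1.0 if normalize else float(ymax),
                        r_squared=r2, n_points=len(V),
                        excluded=not (r2 > r2_gate))


@dataclass
class ModBoltzmannFit:
    """Driving-force-modified Boltzmann fit of the Ca2+ FV relation.

    ``fractional`` is the plain Boltzmann refit of the fractional-activation
    curve (the fitted curve divided by the extrapolated line
    F0 + g_max (V − V_r)).
    """

    F0: float
    g_max: float
    v_half_mV: float
    k_mV: float
    v_r_mV: float
    r_squared: float
    n_points: int
    fractional: BoltzmannFit | None = None
    excluded: bool = False
    converged: bool = True
    no_signal: bool = False

    @property
    def v10_mV(self) -> float:
        return self.v_half_mV - self.k_mV * LN9

    @property
    def dynamic_range_mV(self) -> float:
        return self.k_mV * LN81

    def __call__(self, V):
        V = np.asarray(V, dtype=float)
        return self.F0 + self.g_max * (V - self.v_r_mV) * _boltzmann(
            V, self.v_half_mV, self.k_mV)

    def dff(self, V):
        """Ca2+ fluorescence change above baseline, g_max (V−V_r) P(V).

        Positive below V_r under the negative-gain convention.
        """
        V = np.asarray(V, dtype=float)
        return self.g_max * (V - self.v_r_mV) * _boltzmann(
            V, self.v_half_mV, self.k_mV)

    def fractional_activation(self, V):
        """Fitted curve divided by the extrapolated linear (fully open) fit."""
        V = np.asarray(V, dtype=float)
        return _boltzmann(V, self.v_half_mV, self.k_mV)


def fit_ca_fv(V_mV, F, v_r_mV: float = V_R_MV,
              r2_gate: float = R2_GATE) -> ModBoltzmannFit:
    """Fit the Rhod-FF fluorescence–voltage relation along the ramp.

    V_r is fixed, never fitted.  The gain sign is normalized to the
    negative convention (positive dF below V_r); a positive fitted g_max is
    flipped with a warning.  Flat inputs are flagged ``no_signal``.
    """
    V = np.asarray(V_mV, dtype=float)
    y = np.asarray(F, dtype=float)
    if V.min() > -80 or V.max() < 40:
        log.warning("ramp covers only [%.0f, %.0f] mV", V.min(), V.max())
    spread = y.max() - y.min()
    if spread <= 0 or not np.isfinite(spread):
        return ModBoltzmannFit(np.nan, np.nan, np.nan, np.nan, v_r_mV,
                               np.nan, len(V), excluded=True,
                               converged=False, no_signal=True)

    def model(V, F0, g_max, v_half, k):
        return F0 + g_max * (V - v_r_mV) * _boltzmann(V, v_half, k)

    g0 = -spread / max(v_r_mV - V.min(), 1.0)
    # V_half init: voltage at the half-maximum crossing of the rise
    order = np.argsort(V)
    rise = y[order] - y[order][0]
    above = np.flatnonzero(rise >= 0.5 * rise.max())
    vh0 = float(V[order][above[0]]) if len(above) else -40.0
    best, best_cost = None, np.inf
    for vh_init in (vh0, -45.0, -35.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(model, V, y,
                                    p0=(float(y[order][0]), g0, vh_init, 5.0),
                                    bounds=([-np.inf, -np.inf, -120, 0.5],
                                            [np.inf, np.inf, 60, 60]),
                                    maxfev=20_000)
        except (RuntimeError, ValueError):
            continue
        cost = float(np.sum((y - model(V, *popt)) ** 2))
        if cost < best_cost:
            best, best_cost = popt, cost
    if best is None:
        return ModBoltzmannFit(np.nan, np.nan, np.nan, np.nan, v_r_mV,
                               np.nan, len(V), excluded=True, converged=False)
    F0_f, g_f, vh_f, k_f = (float(p) for p in best)
    if g_f > 0:
        log.warning("fitted g_max > 0; flipping to the negative-gain convention")
        g_f = -g_f
    if abs(g_f) < 1e-12:
        return ModBoltzmannFit(F0_f, g_f, vh_f, k_f, v_r_mV, np.nan, len(V),
                               excluded=True, converged=True, no_signal=True)
    r2 = _r2(y, model(V, F0_f, g_f, vh_f, k_f))
    fit = ModBoltzmannFit(F0=F0_f, g_max=g_f, v_half_mV=vh_f, k_mV=k_f,
                          v_r_mV=v_r_mV, r_squared=r2, n_points=len(V),
                          excluded=not (r2 > r2_gate))
    # fractional activation: divide the fitted curve by the extrapolated
    # line and refit a plain Boltzmann
    grid = np.linspace(min(V.min(), -87.0), min(v_r_mV - 5.0, V.max()), 200)
    pact = fit.fractional_activation(grid)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_boltzmann, grid, pact, p0=(vh_f, k_f),
                                bounds=([-120, 0.1], [60, 60]), maxfev=10_000)
        fit.fractional = BoltzmannFit(
            v_half_mV=float(popt[0]), k_mV=float(popt[1]), amplitude=1.0,
            r_squared=_r2(pact, _boltzmann(grid, *popt)), n_points=len(grid))
    except (RuntimeError, ValueError):
        fit.fractional = None
    return fit


def rhodff_peak(frame_voltages_mV, dff, window_mV=(-17.0, 3.0)) -> float:
    """Peak Rhod-FF dF/F0: mean of the ramp frames with command in ``window_mV``."""
    V = np.asarray(frame_voltages_mV, dtype=float)
    y = np.asarray(dff, dtype=float)
    sel = (V >= window_mV[0]) & (V <= window_mV[1])
    if not sel.any():
        raise FitError(f"no ramp frames with command in {window_mV} mV")
    return float(y[sel].mean())


@dataclass
class CooperativityFit:
    """Power fit release = A·(Ca signal)^m below the 25% release cutoff."""

    m: float
    A: float
    r_squared: float
    n_points: int
    cutoff_fraction: float = COOP_CUTOFF
    source: str = "synaptic_Ca"
    excluded: bool = False
    converged: bool = True


def cooperativity(ca_values, release_values, cutoff: float = COOP_CUTOFF,
                  source: str = "synaptic_Ca",
                  r2_gate: float = R2_GATE) -> CooperativityFit:
    """Fit the apparent Ca2+ cooperativity m from paired curve samples.

    ``ca_values`` and ``release_values`` are the two fitted curves evaluated
    on a common voltage grid (canonically −57…−17 mV in 1 mV steps).  Both
    are normalized to their maximum over the grid; points with release above
    ``cutoff`` of maximum are discarded; ``A·x^m`` is fitted by least
    squares in linear space, initialized from the log-log slope.
    """
    x = np.asarray(ca_values, dtype=float)
    y = np.asarray(release_values, dtype=float)
    if x.max() <= 0 or y.max() <= 0:
        raise FitError("curves must be positive somewhere on the grid")
    x = x / x.max()
    y = y / y.max()
    sel = (y <= cutoff) & (x > 0) & (y > 0)
    if sel.sum() < 3:
        raise FitError(f"fewer than 3 grid points below the {cutoff:.0%} "
                       "release cutoff")
    xs, ys = x[sel], y[sel]
    slope, intercept = np.polyfit(np.log(xs), np.log(ys), 1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(lambda x, A, m: A * x**m, xs, ys,
                                p0=(np.exp(intercept), max(slope, 0.1)),
                                bounds=([0, 0.05], [np.inf, 30]),
                                maxfev=20_000)
    except (RuntimeError, ValueError):
        return CooperativityFit(m=np.nan, A=np.nan, r_squared=np.nan,
                                n_points=int(sel.sum()), source=source,
                                excluded=True, converged=False)
    A_f, m_f = float(popt[0]), float(popt[1])
    r2 = _r2(ys, A_f * xs**m_f)
    return CooperativityFit(m=m_f, A=A_f, r_squared=r2,
                            n_points=int(sel.sum()), source=source,
                            excluded=not (r2 > r2_gate))


def cooperativity_from_fits(ca_fit: ModBoltzmannFit, rel_fit: BoltzmannFit,
                            grid_mV=COOP_GRID_MV, step_mV: float = 1.0,
                            cutoff: float = COOP_CUTOFF,
                            source: str = "synaptic_Ca") -> CooperativityFit:
    """Evaluate both fitted curves on the voltage grid and fit the power law."""
    grid = np.arange(grid_mV[0], grid_mV[1] + step_mV / 2, step_mV)
    return cooperativity(ca_fit.dff(grid), rel_fit(grid), cutoff=cutoff,
                         source=source)


def apparent_cooperativity_truth(syn, duration_ms: float = 50.0,
                                 levels_mV=None, grid_mV=COOP_GRID_MV,
                                 step_mV: float = 1.0,
                                 cutoff: float = COOP_CUTOFF) -> float:
    """Ground-truth *apparent* cooperativity of a synthetic synapse.

    Runs the estimation procedure — Boltzmann fit of the per-step release
    amplitudes, then the power fit against the Ca2+ fluorescence curve on
    the voltage grid — on the generator's exact closed-form responses,
    with no noise and no imaging.  This is what a perfect recording of
    this synapse would measure.  RRP depletion compresses the release–Ca2+
    relation, so the apparent exponent is systematically smaller than the
    rate-law ``m``; parameter-recovery checks therefore compare pipeline
    estimates against this value, while the estimator itself is validated
    separately on constructed exact power-law pairs.
    """
    from .protocols import RELEASE_STEP_LEVELS_MV
    from .synthgen import ca_dff_curve, cumulative_release

    levels = np.asarray(levels_mV if levels_mV is not None
                        else RELEASE_STEP_LEVELS_MV, dtype=float)
    q = cumulative_release(levels, duration_ms, syn)
    rel_fit = fit_release_boltzmann(levels, q)
    if not rel_fit.converged:
        return float("nan")
    grid = np.arange(grid_mV[0], grid_mV[1] + step_mV / 2, step_mV)
    try:
        return cooperativity(ca_dff_curve(grid, syn), rel_fit(grid),
                             cutoff=cutoff).m
    except FitError:
        # synapse already above the release cutoff at the lower grid end
        return float("nan")
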