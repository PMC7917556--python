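"""Ground-truth synthetic experiments.

The study's raw recordings were not deposited, so validation rests on a
forward model that renders complete experiments — two-channel multi-plane
movies plus patch-clamp traces — from known per-synapse parameters.  Every
analysis stage is then testable by parameter recovery.

Forward model
-------------
Ca2+-channel activation at each active zone (AZ) is a Boltzmann
``P(V) = 1 / (1 + exp((V_half - V)/k))`` and the synaptic Ca2+-indicator
(Rhod-FF) fluorescence follows the driving-force-weighted form

    F(V) = F0 + g_max * (V - V_r) * P(V),        V_r = +47.6 mV fixed,

with ``g_max < 0`` so that dF is positive below the reversal potential.
Glutamate release is supralinear in the Ca2+ signal: the instantaneous
release rate is ``lambda(V) = r0 * (dCa(V)/dCa_ref)**m`` with cooperativity
``m``, and cumulative release over a step of duration T follows
readily-releasable-pool (RRP) depletion plus a sustained component

    Q(V, T) = RRP * (1 - exp(-lambda(V) * T)) + s(V) * T,

where the sustained rate carries the same Ca2+ dependence,
``s(V) = s_max * (dCa(V)/dCa_ref)**m``.  The glutamate reporter (iGluSnFR)
responds with a double-exponential kernel ``(1 - e^(-t/tau_on)) e^(-t/tau_off)``.

Rendering adds: 2-D Gaussian spots (sigma 4 px) at the AZ hot spots inside
an elliptical cell, Gaussian axial attenuation of out-of-focus planes
(default FWHM chosen to lose ~25% at ±0.5 um), single-exponential
photobleaching of the iGluSnFR channel, an additive 33.3 Hz spinning-disk
artifact, shot noise (variance = signal/gain) and Gaussian read noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .errors import GenerationError, ParameterError
from .protocols import (VoltageProtocol, make_protocol,
                        RELEASE_STEP_LEVELS_MV, CA_RAMP_RANGE_MV)

V_R_MV = 47.6  # Ca2+ current reversal potential after junction correction

# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass
class SynapseTruth:
    """True parameters of one synapse (one AZ / bouton pair)."""

    synapse_id: int
    v_half_ca_mV: float
    k_ca_mV: float
    g_max: float               # signed gain, a.u. per mV (negative)
    m: float                   # apparent Ca2+ cooperativity
    rrp_au: float              # RRP size in iGluSnFR-AUC units
    tau_depletion_ms: float
    sustained_au_per_s: float
    tau_on_ms: float
    tau_off_ms: float
    position_01: float         # 0 = pillar, 1 = modiolar
    hotspot_xy_px: tuple[float, float] = (0.0, 0.0)
    plane_index: int = 2

    def __post_init__(self):
        if self.k_ca_mV <= 0:
            raise ParameterError("k_ca_mV must be > 0")
        if self.m < 1:
            raise ParameterError("cooperativity m must be >= 1")
        if self.rrp_au < 0:
            raise ParameterError("RRP size must be >= 0")
        if not (0.0 <= self.position_01 <= 1.0):
            raise ParameterError("position_01 must lie in [0, 1]")


@dataclass
class CellTruth:
    """Per-cell geometry, optics and noise."""

    center_xy_px: tuple[float, float] = (104.0, 64.0)
    semi_major_px: float = 42.0
    semi_minor_px: float = 26.0
    angle_rad: float = 0.0
    pillar_sign: int = -1      # pillar vertex at center - a*u (image left)
    v_r_mV: float = V_R_MV
    bleach_tau_s: float = 20.0
    artifact_amp: float = 1.0        # camera counts, 33.3 Hz sinusoid
    read_noise_sd: float = 2.0       # camera counts
    shot_gain: float = 2.0           # counts per photoelectron-equivalent
    offset: float = 10.0             # camera offset (counts)
    cell_fluor: float = 120.0        # Rhod-FF cytosolic fluorescence
    bouton_fluor: float = 150.0      # iGluSnFR resting spot peak

    def major_axis_unit(self) -> np.ndarray:
        return np.array([math.cos(self.angle_rad), math.sin(self.angle_rad)])

    def pillar_vertex(self) -> np.ndarray:
        c = np.asarray(self.center_xy_px, dtype=float)
        return c + self.pillar_sign * self.semi_major_px * self.major_axis_unit()

    def modiolar_vertex(self) -> np.ndarray:
        c = np.asarray(self.center_xy_px, dtype=float)
        return c - self.pillar_sign * self.semi_major_px * self.major_axis_unit()

    def contains(self, xy, margin: float = 0.0) -> bool:
        u = self.major_axis_unit()
        v = np.array([-u[1], u[0]])
        d = np.asarray(xy, dtype=float) - np.asarray(self.center_xy_px)
        a = self.semi_major_px - margin
        b = self.semi_minor_px - margin
        return (d @ u) ** 2 / a**2 + (d @ v) ** 2 / b**2 <= 1.0


@dataclass
class GroundTruthSet:
    """All true parameters of one synthetic cell experiment."""

    cell: CellTruth
    synapses: list[SynapseTruth]
    seed: int = 0

    def __len__(self):
        return len(self.synapses)

    def to_frame(self):
        import pandas as pd
        rows = []
        for s in self.synapses:
            d = asdict(s)
            d["hotspot_x_px"], d["hotspot_y_px"] = d.pop("hotspot_xy_px")
            rows.append(d)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps({"cell": asdict(self.cell),
                           "synapses": [asdict(s) for s in self.synapses],
                           "seed": self.seed}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthSet":
        d = json.loads(text)
        cell = CellTruth(**{**d["cell"],
                            "center_xy_px": tuple(d["cell"]["center_xy_px"])})
        syns = [SynapseTruth(**{**s, "hotspot_xy_px": tuple(s["hotspot_xy_px"])})
                for s in d["synapses"]]
        return cls(cell=cell, synapses=syns, seed=d.get("seed", 0))


@dataclass
class GradientParams:
    """Distributional parameters of the synapse population.

    ``v_half_pillar_mV + slope_mV * position`` plus Gaussian scatter plants
    the pillar→modiolar half-activation gradient (pillar synapses activate
    at more negative potentials).  ``m_components`` mixes nanodomain-like
    (low m) and microdomain-like (high m) synapses.
    """

    v_half_pillar_mV: float = -45.0
    slope_mV: float = 8.0
    v_half_scatter_sd_mV: float = 3.0
    k_mean_mV: float = 5.0
    k_sd_mV: float = 0.7
    g_max_mean: float = -0.020     # a.u./mV
    g_max_sd: float = 0.004
    m_components: tuple[tuple[float, float], ...] = (
        (1.6, 0.50), (3.2, 0.35), (6.1, 0.15))
    m_jitter_sd: float = 0.25
    rrp_mean_au: float = 2.3       # ~10 SV x 0.23 a.u./SV
    rrp_sd_au: float = 0.5
    tau_depletion_mean_ms: float = 11.0
    tau_depletion_sd_ms: float = 2.0
    sustained_mean_au_per_s: float = 42.7
    sustained_sd_au_per_s: float = 8.0
    tau_on_mean_ms: float = 10.0
    tau_off_mean_ms: float = 90.0
    kinetics_rel_sd: float = 0.15

    def __post_init__(self):
        for name in ("v_half_scatter_sd_mV", "k_sd_mV", "g_max_sd",
                     "m_jitter_sd", "rrp_sd_au", "tau_depletion_sd_ms",
                     "sustained_sd_au_per_s", "kinetics_rel_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


def sample_ground_truth(n_synapses: int, gradient: GradientParams | None = None,
                        seed: int = 0, cell: CellTruth | None = None,
                        min_separation_px: float = 14.0) -> GroundTruthSet:
    """Draw one cell's ground truth from the population distributions.

    Hot spots are placed inside the cell ellipse at the along-axis
    coordinate implied by ``position_01``, with at least
    ``min_separation_px`` between spots so that segmentation failures are
    attributable to the segmenter, not to coincident truth.
    """
    if n_synapses < 1:
        raise ParameterError("n_synapses must be >= 1")
    g = gradient or GradientParams()
    cell = cell or CellTruth()
    rng = np.random.default_rng(seed)

    comps = np.array([c[0] for c in g.m_components])
    weights = np.array([c[1] for c in g.m_components], dtype=float)
    weights = weights / weights.sum()

    syns: list[SynapseTruth] = []
    placed: list[np.ndarray] = []
    u = cell.major_axis_unit()
    v = np.array([-u[1], u[0]])
    pillar = cell.pillar_vertex()
    axis_vec = cell.modiolar_vertex() - pillar
    for i in range(n_synapses):
        pos = float(rng.uniform(0.08, 0.92))
        # place on the axis, offset across the minor axis but inside the
        # ellipse; if the cell is too crowded for the requested separation,
        # relax it geometrically rather than failing (dense cells exist)
        sep = min_separation_px
        xy = None
        for attempt in range(1000):
            half_width = cell.semi_minor_px * math.sqrt(
                max(1e-6, 1.0 - (2 * pos - 1.0) ** 2))
            off = rng.uniform(-0.75, 0.75) * half_width
            cand = pillar + pos * axis_vec + off * v
            if cell.contains(cand, margin=3.0) and all(
                    np.linalg.norm(cand - p) >= sep for p in placed):
                xy = cand
                break
            pos = float(rng.uniform(0.08, 0.92))
            if attempt and attempt % 100 == 0:
                sep *= 0.7
        if xy is None:
            raise GenerationError("could not place hot spots inside the "
                                  "ellipse")
        placed.append(xy)

        m = float(rng.choice(comps, p=weights) + rng.normal(0, g.m_jitter_sd))
        syns.append(SynapseTruth(
            synapse_id=i,
            v_half_ca_mV=float(g.v_half_pillar_mV + g.slope_mV * pos
                               + rng.normal(0, g.v_half_scatter_sd_mV)),
            k_ca_mV=float(max(2.0, rng.normal(g.k_mean_mV, g.k_sd_mV))),
            g_max=float(min(-0.005, rng.normal(g.g_max_mean, g.g_max_sd))),
            m=max(1.0, m),
            rrp_au=float(max(0.5, rng.normal(g.rrp_mean_au, g.rrp_sd_au))),
            tau_depletion_ms=float(max(3.0, rng.normal(
                g.tau_depletion_mean_ms, g.tau_depletion_sd_ms))),
            sustained_au_per_s=float(max(5.0, rng.normal(
                g.sustained_mean_au_per_s, g.sustained_sd_au_per_s))),
            tau_on_ms=float(max(2.0, g.tau_on_mean_ms *
                                rng.normal(1.0, g.kinetics_rel_sd))),
            tau_off_ms=float(max(10.0, g.tau_off_mean_ms *
                                 rng.normal(1.0, g.kinetics_rel_sd))),
            position_01=pos,
            hotspot_xy_px=(float(xy[0]), float(xy[1])),
            plane_index=int(rng.integers(0, 5)),
        ))
    return GroundTruthSet(cell=cell, synapses=syns, seed=seed)


# ---------------------------------------------------------------------------
# Closed-form response curves (these double as oracles for the renderer)


def boltzmann_activation(V, v_half_mV, k_mV):
    """Ca2+-channel open probability ``1 / (1 + exp((V_half - V)/k))``."""
    V = np.asarray(V, dtype=float)
    return 1.0 / (1.0 + np.exp((v_half_mV - V) / k_mV))


def ca_dff_curve(V, syn: SynapseTruth, v_r_mV: float = V_R_MV):
    """Synaptic Ca2+ fluorescence change ``g_max (V - V_r) P(V)``.

    With the negative-gain convention (g_max < 0) this is positive below
    the reversal potential.
    """
    V = np.asarray(V, dtype=float)
    return syn.g_max * (V - v_r_mV) * boltzmann_activation(
        V, syn.v_half_ca_mV, syn.k_ca_mV)


#: Voltage of the pool-dynamics protocol (duration series); the depletion
#: time constant tau_depletion_ms is defined at this potential.
POOL_LEVEL_MV = -23.0


def _dca_ref(syn: SynapseTruth, v_r_mV: float) -> float:
    return float(ca_dff_curve(POOL_LEVEL_MV, syn, v_r_mV))


def release_rate(V, syn: SynapseTruth, v_r_mV: float = V_R_MV):
    """Instantaneous release rate (1/s).

    ``lambda(V) = (1/tau_depletion) * (dCa(V)/dCa(-23 mV))**m``: the power
    law referenced so that a step to the pool-protocol potential depletes
    the RRP with exactly the synapse's tau_depletion_ms.
    """
    dca = np.maximum(ca_dff_curve(V, syn, v_r_mV), 0.0)
    r_ref = 1000.0 / syn.tau_depletion_ms
    return r_ref * (dca / _dca_ref(syn, v_r_mV)) ** syn.m


def cumulative_release(V, duration_ms, syn: SynapseTruth,
                       v_r_mV: float = V_R_MV):
    """Cumulative release Q(V, T) = RRP (1 - e^(-lambda T)) + s(V) T (a.u.).

    The sustained rate carries the fast component's Ca2+ dependence
    (``s(V) = s_ref * (dCa/dCa_ref)**m``), so at fixed voltage the duration
    dependence is exactly the exponential-plus-line the pool fit assumes,
    and across voltages the sub-saturation relation is a power law in the
    Ca2+ signal.  At saturating rates the fast component is compressed by
    depletion, which makes the *apparent* cooperativity measured from
    release-vs-Ca curves smaller than ``m`` (see the methods note).
    """
    lam = release_rate(V, syn, v_r_mV)
    T = np.asarray(duration_ms, dtype=float) / 1000.0
    dca = np.maximum(ca_dff_curve(V, syn, v_r_mV), 0.0)
    s = syn.sustained_au_per_s * (dca / _dca_ref(syn, v_r_mV)) ** syn.m
    return syn.rrp_au * (1.0 - np.exp(-lam * T)) + s * T


def indicator_kernel(t_ms, tau_on_ms, tau_off_ms):
    """iGluSnFR impulse response ``(1 - e^(-t/tau_on)) e^(-t/tau_off)``, 0 for t<0."""
    t = np.asarray(t_ms, dtype=float)
    k = (1.0 - np.exp(-t / tau_on_ms)) * np.exp(-t / tau_off_ms)
    return np.where(t >= 0, k, 0.0)


def axial_attenuation(dz_um, fwhm_um: float = 1.55):
    """Gaussian out-of-focus attenuation; default FWHM loses ~25% at 0.5 um."""
    sigma = fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-np.asarray(dz_um, dtype=float) ** 2 / (2.0 * sigma**2))


# ---------------------------------------------------------------------------
# Acquisition and rendering


@dataclass
class AcquisitionParams:
    """Camera/stage parameters of the synthetic rig."""

    frame_shape: tuple[int, int] = (128, 160)   # rows, cols
    pixel_size_nm: float = 103.0
    n_planes: int = 5
    plane_spacing_um: float = 0.5
    rate_iglusnfr_hz: float = 50.0
    rate_rhodff_hz: float = 100.0
    baseline_frames: int = 15
    response_frames: int = 40      # post-onset frames kept (AUC window)
    tail_frames: int = 5
    spot_sigma_px: float = 4.0
    axial_fwhm_um: float = 1.55
    dff_scale: float = 0.5         # peak dF/F0 per a.u. of release
    rhod_scale: float = 120.0      # counts per a.u. of Ca dF
    artifact_hz: float = 100.0 / 3.0   # spinning disk at 2,000 rpm

    def __post_init__(self):
        if self.rate_iglusnfr_hz <= 0 or self.rate_rhodff_hz <= 0:
            raise ParameterError("acquisition rates must be positive")


@dataclass
class Sweep:
    """One recorded sweep: a movie per plane plus its stimulus annotation."""

    movie: np.ndarray              # (n_planes, n_frames, rows, cols)
    rate_hz: float
    timestamps_s: np.ndarray       # (n_frames,) from sweep start
    stim_onset_index: int
    stim: dict

    @property
    def n_frames(self) -> int:
        return self.movie.shape[1]


@dataclass
class EphysSweep:
    time_s: np.ndarray
    command_mV: np.ndarray
    current_pA: np.ndarray
    cm_fF: np.ndarray | None
    stim: dict


@dataclass
class EphysTraces:
    """Patch-clamp traces aligned to the command, one entry per sweep."""

    sweeps: list[EphysSweep]
    rate_hz: float
    leak_pA: float = 0.0


@dataclass
class RecordingBundle:
    """A full synthetic experiment: both channels, protocols, ephys, truth."""

    channels: dict[str, list[Sweep]]
    protocols: dict[str, VoltageProtocol]
    ephys: EphysTraces | None = None
    pixel_size_nm: float = 103.0
    plane_spacing_um: float = 0.5
    ground_truth: GroundTruthSet | None = None


def _spot_profile(shape, xy, sigma):
    """2-D Gaussian spot (peak 1) evaluated over a local window.

    Returns (row slice, col slice, patch) so callers can add it in place.
    """
    rows, cols = shape
    x0, y0 = xy
    half = int(math.ceil(4 * sigma))
    r0, r1 = int(y0) - half, int(y0) + half + 1
    c0, c1 = int(x0) - half, int(x0) + half + 1
    if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
        raise GenerationError(f"spot at {xy} (±{half} px) falls outside the "
                              f"{rows}x{cols} frame")
    yy, xx = np.mgrid[r0:r1, c0:c1]
    patch = np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2))
    return slice(r0, r1), slice(c0, c1), patch


def _ellipse_mask(shape, cell: CellTruth, soft_px: float = 2.0):
    """Soft-edged filled ellipse (0..1) for the cytosolic indicator scene."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    u = cell.major_axis_unit()
    dx = xx - cell.center_xy_px[0]
    dy = yy - cell.center_xy_px[1]
    du = dx * u[0] + dy * u[1]
    dv = -dx * u[1] + dy * u[0]
    r = np.sqrt((du / cell.semi_major_px) ** 2 + (dv / cell.semi_minor_px) ** 2)
    # 0..1 transition over ~soft_px at the boundary
    scale = soft_px / max(cell.semi_minor_px, 1.0)
    return 1.0 / (1.0 + np.exp((r - 1.0) / max(scale, 1e-6)))


def _apply_noise(stack, cell: CellTruth, rng):
    """Shot noise (variance = signal/gain) plus Gaussian read noise, in place."""
    if cell.shot_gain < 0 or cell.read_noise_sd < 0:
        raise ParameterError("noise parameters must be >= 0")
    if cell.shot_gain > 0:
        stack += rng.standard_normal(stack.shape) * np.sqrt(
            np.maximum(stack, 0.0) / cell.shot_gain)
    if cell.read_noise_sd > 0:
        stack += rng.standard_normal(stack.shape) * cell.read_noise_sd
    np.maximum(stack, 0.0, out=stack)


def render_movie(gt: GroundTruthSet, protocol: VoltageProtocol,
                 acq: AcquisitionParams | None = None, seed: int = 0,
                 noise: bool = True) -> RecordingBundle:
    """Render the channel driven by ``protocol``.

    * step protocol → iGluSnFR channel, 50 Hz, single (central) plane,
      one sweep per step level in the protocol's pseudo-random order;
    * ramp protocol → Rhod-FF channel, 100 Hz, one sweep covering all
      ``n_planes`` (plane-resolved stack in each sweep).

    ``noise=False`` disables bleaching, the periodic artifact and all noise,
    leaving the deterministic scene (used by oracle tests).
    """
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(seed)
    cell = gt.cell
    shape = acq.frame_shape

    if protocol.kind == "step":
        sweeps = [
            _render_step_sweep(gt, level, protocol.duration_ms, acq, cell,
                               rng, noise)
            for level in protocol.ordered_levels()
        ]
        return RecordingBundle(channels={"iGluSnFR": sweeps},
                               protocols={"iGluSnFR": protocol},
                               pixel_size_nm=acq.pixel_size_nm,
                               plane_spacing_um=acq.plane_spacing_um,
                               ground_truth=gt)
    if protocol.kind == "ramp":
        sweep = _render_ramp_sweep(gt, protocol, acq, cell, rng, noise)
        return RecordingBundle(channels={"RhodFF": [sweep]},
                               protocols={"RhodFF": protocol},
                               pixel_size_nm=acq.pixel_size_nm,
                               plane_spacing_um=acq.plane_spacing_um,
                               ground_truth=gt)
    raise ParameterError(f"cannot render protocol kind {protocol.kind!r}")


def _render_step_sweep(gt, level_mV, duration_ms, acq, cell, rng, noise):
    dt = 1.0 / acq.rate_iglusnfr_hz
    n_frames = acq.baseline_frames + acq.response_frames + acq.tail_frames
    t = np.arange(n_frames) * dt
    onset = acq.baseline_frames
    t_since_ms = (t - t[onset]) * 1000.0

    base = np.full(acq.frame_shape, cell.offset, dtype=float)
    stack = np.broadcast_to(base, (n_frames,) + acq.frame_shape).copy()

    for syn in gt.synapses:
        rs, cs, patch = _spot_profile(acq.frame_shape, syn.hotspot_xy_px,
                                      acq.spot_sigma_px)
        q = float(cumulative_release(level_mV, duration_ms, syn,
                                     cell.v_r_mV))
        kern = indicator_kernel(t_since_ms, syn.tau_on_ms, syn.tau_off_ms)
        amp = cell.bouton_fluor * (1.0 + acq.dff_scale * q * kern)
        stack[:, rs, cs] += amp[:, None, None] * patch

    if noise:
        fluor = stack - cell.offset
        fluor *= np.exp(-t / cell.bleach_tau_s)[:, None, None]
        stack = cell.offset + fluor
        stack += (cell.artifact_amp *
                  np.sin(2 * np.pi * acq.artifact_hz * t))[:, None, None]
        _apply_noise(stack, cell, rng)

    return Sweep(movie=stack[None, ...], rate_hz=acq.rate_iglusnfr_hz,
                 timestamps_s=t, stim_onset_index=onset,
                 stim={"kind": "step", "level_mV": float(level_mV),
                       "duration_ms": float(duration_ms)})


def _render_ramp_sweep(gt, protocol, acq, cell, rng, noise):
    dt = 1.0 / acq.rate_rhodff_hz
    ramp_frames = int(round(protocol.ramp_duration_ms / 1000.0 / dt))
    n_frames = acq.baseline_frames + ramp_frames + acq.tail_frames
    t = np.arange(n_frames) * dt
    onset = acq.baseline_frames
    t_since_ms = (t - t[onset]) * 1000.0

    # frame voltage: command at mid-exposure during the ramp, holding outside
    v = np.full(n_frames, protocol.holding_mV)
    in_ramp = (t_since_ms >= 0) & (t_since_ms < protocol.ramp_duration_ms)
    v[in_ramp] = protocol.ramp_voltage(t_since_ms[in_ramp] + 1000.0 * dt / 2.0)
    v[t_since_ms >= protocol.ramp_duration_ms] = protocol.holding_mV

    base = cell.offset + cell.cell_fluor * _ellipse_mask(acq.frame_shape, cell)
    planes = np.empty((acq.n_planes,) + (n_frames,) + acq.frame_shape)
    for p in range(acq.n_planes):
        stack = np.broadcast_to(base, (n_frames,) + acq.frame_shape).copy()
        for syn in gt.synapses:
            att = float(axial_attenuation(
                (p - syn.plane_index) * acq.plane_spacing_um,
                acq.axial_fwhm_um))
            rs, cs, patch = _spot_profile(acq.frame_shape, syn.hotspot_xy_px,
                                          acq.spot_sigma_px)
            dca = ca_dff_curve(v, syn, cell.v_r_mV)
            dca[~in_ramp] = 0.0
            amp = acq.rhod_scale * att * dca
            stack[:, rs, cs] += amp[:, None, None] * patch
        if noise:
            stack += (cell.artifact_amp *
                      np.sin(2 * np.pi * acq.artifact_hz * t))[:, None, None]
            _apply_noise(stack, cell, rng)
        planes[p] = stack

    return Sweep(movie=planes, rate_hz=acq.rate_rhodff_hz,
                 timestamps_s=t, stim_onset_index=onset,
                 stim={"kind": "ramp",
                       "range_mV": list(protocol.ramp_range_mV),
                       "rate_mV_per_ms": protocol.ramp_rate_mV_per_ms,
                       "frame_voltage_mV": v.tolist()})


def render_experiment(gt: GroundTruthSet, acq: AcquisitionParams | None = None,
                      seed: int = 0, noise: bool = True,
                      step_levels=RELEASE_STEP_LEVELS_MV,
                      step_duration_ms: float = 50.0) -> RecordingBundle:
    """Render the full dual-color experiment (ramp Ca2+ + step release)."""
    acq = acq or AcquisitionParams()
    step = make_protocol("step", levels_mV=step_levels,
                         duration_ms=step_duration_ms, seed=seed)
    ramp = make_protocol("ramp")
    b_step = render_movie(gt, step, acq, seed=seed, noise=noise)
    b_ramp = render_movie(gt, ramp, acq, seed=seed + 1, noise=noise)
    ephys = synth_ephys(gt, step, seed=seed + 2)
    return RecordingBundle(
        channels={**b_step.channels, **b_ramp.channels},
        protocols={**b_step.protocols, **b_ramp.protocols},
        ephys=ephys, pixel_size_nm=acq.pixel_size_nm,
        plane_spacing_um=acq.plane_spacing_um, ground_truth=gt)


# ---------------------------------------------------------------------------
# Trace-level rendering (ROI-mean signals without the imaging step)


def ramp_dff_trace(syn: SynapseTruth, cell: CellTruth,
                   protocol: VoltageProtocol, acq: AcquisitionParams,
                   rng, noise_sd: float = 0.02):
    """ROI-mean dF/F0 Rhod-FF trace along the ramp, plus its frame voltages.

    Emulates the trace a perfectly segmented ROI would yield: the
    closed-form Ca2+ fluorescence curve sampled at the frame times with the
    periodic artifact and Gaussian noise of SD ``noise_sd`` (dF/F0 units).
    """
    dt = 1.0 / acq.rate_rhodff_hz
    ramp_frames = int(round(protocol.ramp_duration_ms / 1000.0 / dt))
    n_frames = acq.baseline_frames + ramp_frames + acq.tail_frames
    t = np.arange(n_frames) * dt
    t_since_ms = (t - t[acq.baseline_frames]) * 1000.0
    v = np.full(n_frames, protocol.holding_mV)
    in_ramp = (t_since_ms >= 0) & (t_since_ms < protocol.ramp_duration_ms)
    v[in_ramp] = protocol.ramp_voltage(t_since_ms[in_ramp] + 1000.0 * dt / 2.0)
    dff = acq.dff_scale * ca_dff_curve(v, syn, cell.v_r_mV)
    dff[~in_ramp] = 0.0
    dff = dff + (cell.artifact_amp / cell.cell_fluor) * np.sin(
        2 * np.pi * acq.artifact_hz * t)
    if noise_sd > 0:
        dff = dff + rng.normal(0, noise_sd, n_frames)
    return t, dff, v


def step_auc_responses(syn: SynapseTruth, cell: CellTruth, levels_mV,
                       duration_ms: float, rng, noise_sd: float = 0.012):
    """Per-step iGluSnFR-AUC responses (a.u.) at ROI-trace noise levels.

    Noise is additive with SD ``noise_sd`` x max response, which matches
    the empirical AUC scatter that the movie renderer's default shot/read
    noise produces after ROI averaging and the 40-frame integration
    (measured by repeated renders of one synapse: SD ~1.2% of the maximal
    response, independent of step level).
    """
    q = cumulative_release(np.asarray(levels_mV, float), duration_ms, syn,
                           cell.v_r_mV)
    if noise_sd > 0:
        q = q + rng.normal(0, noise_sd * q.max(), q.shape)
    return q


# ---------------------------------------------------------------------------
# Electrophysiology


def synth_ephys(gt: GroundTruthSet, protocol: VoltageProtocol, seed: int = 0,
                rate_hz: float = 10_000.0, leak_pA: float = 0.0,
                current_gain_pA: float = 400.0, cap_gain_fF_per_au: float = 1.0,
                noise_pA: float = 2.0, cm_noise_fF: float = 1.0) -> EphysTraces:
    """Whole-cell current and capacitance traces for ``protocol``.

    The Ca2+ current is the sum over AZ conductances,
    ``I(t) = leak + sum_i current_gain * g_max_i * P_i(V) * (V - V_r)`` (pA),
    and the capacitance trace steps at stimulus end by the summed cumulative
    release times ``cap_gain_fF_per_au``.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    cell = gt.cell
    sweeps = []

    def current_of(v):
        i = np.full_like(v, leak_pA, dtype=float)
        for syn in gt.synapses:
            i += (current_gain_pA * syn.g_max *
                  boltzmann_activation(v, syn.v_half_ca_mV, syn.k_ca_mV) *
                  (v - cell.v_r_mV))
        return i

    if protocol.kind == "step":
        pre_s, post_s = 0.6, 0.6   # margins for the C_m windows
        for level in protocol.ordered_levels():
            T = protocol.duration_ms / 1000.0
            n = int(round((pre_s + T + post_s) / dt))
            t = np.arange(n) * dt
            v = np.full(n, protocol.holding_mV)
            # closed interval so the trapezoid over the step is exact
            in_step = (t >= pre_s) & (t <= pre_s + T + 1e-12)
            v[in_step] = level
            i = current_of(v) + rng.normal(0, noise_pA, n)
            q = float(sum(float(cumulative_release(
                level, protocol.duration_ms, s, cell.v_r_mV))
                for s in gt.synapses))
            cm = np.where(t >= pre_s + T, q * cap_gain_fF_per_au, 0.0)
            cm = cm + rng.normal(0, cm_noise_fF, n)
            sweeps.append(EphysSweep(time_s=t, command_mV=v, current_pA=i,
                                     cm_fF=cm,
                                     stim={"kind": "step",
                                           "level_mV": float(level),
                                           "duration_ms": protocol.duration_ms,
                                           "onset_s": pre_s}))
    elif protocol.kind == "ramp":
        pre_s, post_s = 0.1, 0.1
        T = protocol.ramp_duration_ms / 1000.0
        n = int(round((pre_s + T + post_s) / dt))
        t = np.arange(n) * dt
        v = np.full(n, protocol.holding_mV)
        in_ramp = (t >= pre_s) & (t < pre_s + T)
        v[in_ramp] = protocol.ramp_voltage((t[in_ramp] - pre_s) * 1000.0)
        i = current_of(v) + rng.normal(0, noise_pA, n)
        sweeps.append(EphysSweep(time_s=t, command_mV=v, current_pA=i,
                                 cm_fF=None,
                                 stim={"kind": "ramp", "onset_s": pre_s,
                                       "duration_ms": protocol.ramp_duration_ms}))
    else:
        raise ParameterError(f"unknown protocol kind {protocol.kind!r}")
    return EphysTraces(sweeps=sweeps, rate_hz=rate_hz, leak_pA=leak_pA)


def true_qca_pC(gt: GroundTruthSet, level_mV: float, duration_ms: float,
                current_gain_pA: float = 400.0) -> float:
    """Closed-form Ca2+ charge for a step (pA x s = pC); oracle for ``qca``."""
    i = sum(current_gain_pA * syn.g_max *
            float(boltzmann_activation(level_mV, syn.v_half_ca_mV, syn.k_ca_mV)) *
            (level_mV - gt.cell.v_r_mV) for syn in gt.synapses)
    return i * duration_ms / 1000.0
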