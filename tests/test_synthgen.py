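"""The generator is the ground-truth source for everything else, so its own
contracts (determinism, conservation, closed-form consistency) are tested
against direct evaluation of its model equations."""

import numpy as np
import pytest

import ihcsynapse as ihc
from ihcsynapse.errors import GenerationError, ParameterError
from ihcsynapse.fvfit import cooperativity
from ihcsynapse.protocols import RELEASE_STEP_LEVELS_MV, make_protocol
from ihcsynapse.synthgen import (AcquisitionParams, CellTruth, GradientParams,
                                 SynapseTruth, axial_attenuation,
                                 boltzmann_activation, ca_dff_curve,
                                 cumulative_release, render_movie,
                                 sample_ground_truth, synth_ephys,
                                 true_qca_pC)


def _plain_synapse(**overrides):
    defaults = dict(synapse_id=0, v_half_ca_mV=-41.0, k_ca_mV=5.0,
                    g_max=-0.02, m=1.0, rrp_au=2.3, tau_depletion_ms=11.0,
                    sustained_au_per_s=42.7, tau_on_ms=10.0, tau_off_ms=90.0,
                    position_01=0.5, hotspot_xy_px=(100.0, 64.0),
                    plane_index=2)
    defaults.update(overrides)
    return SynapseTruth(**defaults)


class TestGroundTruthSampling:
    def test_seeded_determinism_is_bit_identical(self):
        a = sample_ground_truth(55, seed=7)
        b = sample_ground_truth(55, seed=7)
        assert a.to_json() == b.to_json()
        assert len(a) == 55

    def test_invariants_hold_for_every_synapse(self):
        gt = sample_ground_truth(80, seed=3)
        for s in gt.synapses:
            assert s.k_ca_mV > 0
            assert s.m >= 1
            assert s.rrp_au >= 0
            assert 0 <= s.position_01 <= 1
            assert gt.cell.contains(s.hotspot_xy_px)

    def test_null_gradient_leaves_position_uncorrelated(self):
        g = GradientParams(slope_mV=0.0)
        gt = sample_ground_truth(120, gradient=g, seed=11)
        df = gt.to_frame()
        r = np.corrcoef(df.position_01, df.v_half_ca_mV)[0, 1]
        assert abs(r) < 0.2

    def test_planted_gradient_recovered_by_ols(self):
        # independent oracle: ordinary least squares on the generated table
        g = GradientParams(slope_mV=8.0, v_half_scatter_sd_mV=2.0)
        gt = sample_ground_truth(200, gradient=g, seed=5,
                                 min_separation_px=2.0)
        df = gt.to_frame()
        slope, _ = np.polyfit(df.position_01, df.v_half_ca_mV, 1)
        # OLS standard error of the slope
        resid = df.v_half_ca_mV - np.polyval(
            np.polyfit(df.position_01, df.v_half_ca_mV, 1), df.position_01)
        sxx = np.sum((df.position_01 - df.position_01.mean()) ** 2)
        se = np.sqrt(np.sum(resid**2) / (len(df) - 2) / sxx)
        assert abs(slope - 8.0) < 3 * se

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ParameterError):
            GradientParams(v_half_scatter_sd_mV=-1.0)
        with pytest.raises(ParameterError):
            sample_ground_truth(0)


class TestForwardModel:
    def test_release_is_monotone_up_to_the_ca_influx_peak(self):
        # the driving-force-weighted Ca signal peaks near −28 mV (activation
        # saturates while the driving force keeps shrinking), so release is
        # strictly monotone below the peak and nearly flat above it
        syn = _plain_synapse(m=2.5)
        v = np.arange(-62.0, -28.5, 1.0)
        q = cumulative_release(v, 50.0, syn)
        assert np.all(np.diff(q) > 0)
        q_top = cumulative_release(np.array([-25.0, -17.0]), 50.0, syn)
        assert q_top[1] > 0.75 * q_top[0]

    def test_cumulative_release_never_exceeds_pool_plus_sustained(self):
        syn = _plain_synapse(m=3.0)
        for T in (2.0, 10.0, 50.0, 100.0):
            v = np.arange(-62.0, 60.0, 1.0)
            q = cumulative_release(v, T, syn)
            s_max = syn.sustained_au_per_s * (
                np.max(np.maximum(ca_dff_curve(v, syn), 0)) /
                ca_dff_curve(-23.0, syn)) ** syn.m
            assert np.all(q <= syn.rrp_au + s_max * T / 1000.0 + 1e-9)

    def test_linear_coupling_without_depletion_yields_unity_exponent(self):
        # m = 1 and negligible depletion force release ∝ Ca signal; the
        # power fit on the closed-form curves must return 1.0 ± 0.05
        syn = _plain_synapse(m=1.0, tau_depletion_ms=1e6,
                             sustained_au_per_s=0.0, rrp_au=1e7)
        grid = np.arange(-57.0, -16.5, 1.0)
        fit = cooperativity(ca_dff_curve(grid, syn),
                            cumulative_release(grid, 50.0, syn))
        assert fit.m == pytest.approx(1.0, abs=0.05)

    def test_axial_attenuation_default_loses_quarter_at_half_micron(self):
        assert axial_attenuation(0.5) == pytest.approx(0.75, abs=0.01)
        assert axial_attenuation(0.0) == 1.0


class TestRenderMovie:
    def test_zero_synapses_zero_noise_gives_constant_frames(self):
        gt = ihc.GroundTruthSet(cell=CellTruth(), synapses=[], seed=0)
        step = make_protocol("step", levels_mV=[-17.0], seed=0)
        b = render_movie(gt, step, seed=0, noise=False)
        movie = b.channels["iGluSnFR"][0].movie
        assert np.ptp(movie) == 0.0
        ramp = make_protocol("ramp")
        b2 = render_movie(gt, ramp, seed=0, noise=False)
        m2 = b2.channels["RhodFF"][0].movie
        # every frame identical to the first (static cell scene)
        assert np.allclose(m2, m2[:, :1])

    def test_rendering_is_seed_deterministic(self):
        gt = sample_ground_truth(2, seed=4)
        step = make_protocol("step", levels_mV=[-33.0, -17.0], seed=0)
        a = render_movie(gt, step, seed=9).channels["iGluSnFR"]
        b = render_movie(gt, step, seed=9).channels["iGluSnFR"]
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.movie, sb.movie)

    def test_noiseless_step_response_monotone_in_level(self):
        gt = sample_ground_truth(1, seed=2)
        step = make_protocol("step", levels_mV=RELEASE_STEP_LEVELS_MV, seed=0)
        b = render_movie(gt, step, seed=0, noise=False)
        peaks = {sw.stim["level_mV"]: sw.movie.max() for sw
                 in b.channels["iGluSnFR"]}
        levels = sorted(peaks)
        vals = np.array([peaks[v] for v in levels])
        # strictly monotone below the Ca-influx peak (≈ −28 mV), and the
        # strongest steps stay within a few percent of the maximum
        below = vals[np.array(levels) <= -29.0]
        assert np.all(np.diff(below) >= 0)
        assert vals[-1] >= 0.9 * vals.max()

    def test_spot_outside_frame_raises(self):
        cell = CellTruth(center_xy_px=(10.0, 10.0), semi_major_px=30,
                         semi_minor_px=20)
        syn = _plain_synapse(hotspot_xy_px=(2.0, 2.0))
        gt = ihc.GroundTruthSet(cell=cell, synapses=[syn], seed=0)
        step = make_protocol("step", levels_mV=[-17.0], seed=0)
        with pytest.raises(GenerationError):
            render_movie(gt, step, seed=0, noise=False)


class TestSynthEphys:
    def test_zero_conductance_gives_zero_charge(self):
        gt = ihc.GroundTruthSet(cell=CellTruth(), synapses=[], seed=0)
        step = make_protocol("step", levels_mV=[-23.0], duration_ms=10.0)
        tr = synth_ephys(gt, step, seed=0, noise_pA=0.0)
        sw = tr.sweeps[0]
        on = sw.stim["onset_s"]
        q = ihc.qca(sw.time_s, sw.current_pA, (on, on + 0.010))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_single_synapse_charge_matches_closed_form(self):
        syn = _plain_synapse()
        gt = ihc.GroundTruthSet(cell=CellTruth(), synapses=[syn], seed=0)
        step = make_protocol("step", levels_mV=[-23.0], duration_ms=10.0)
        tr = synth_ephys(gt, step, seed=0, noise_pA=0.0)
        sw = tr.sweeps[0]
        on = sw.stim["onset_s"]
        q = ihc.qca(sw.time_s, sw.current_pA, (on, on + 0.010))
        expected = true_qca_pC(gt, -23.0, 10.0)
        assert q == pytest.approx(expected, rel=1e-3)

    def test_capacitance_step_saturates_at_full_pool(self):
        # RRP 10 units, tau 10 ms, no sustained: a 100-ms step releases
        # RRP·(1−e^{−10}) ≈ the whole pool
        syn = _plain_synapse(rrp_au=10.0, tau_depletion_ms=10.0,
                             sustained_au_per_s=0.0)
        gt = ihc.GroundTruthSet(cell=CellTruth(), synapses=[syn], seed=0)
        step = make_protocol("step", levels_mV=[-23.0], duration_ms=100.0)
        tr = synth_ephys(gt, step, seed=0, noise_pA=0.0, cm_noise_fF=0.0)
        sw = tr.sweeps[0]
        on = sw.stim["onset_s"]
        dcm = ihc.delta_cm(sw.time_s, sw.cm_fF, (on, on + 0.100))
        assert dcm == pytest.approx(10.0 * (1 - np.exp(-10.0)), rel=1e-6)
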