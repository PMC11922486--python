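import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from qcucvp import (
    ForwardInputs,
    TimeSeries,
    VesselParams,
    estimate_cvp_waveform,
    forward_areas,
    invert_frame,
    synth_capture,
)
from qcucvp.inverse_model import tube_law_area, tube_law_pressure
from qcucvp.synthetic_data import COMPONENT_PHASE
from conftest import hold_window


VESSEL = VesselParams()


class TestTubeLaw:
    def test_reference_area_at_zero_transmural(self):
        assert tube_law_area(0.0, VESSEL) == pytest.approx(VESSEL.a_ref)

    def test_strictly_increasing(self):
        p = np.linspace(-30, 30, 1201)
        a = tube_law_area(p, VESSEL)
        assert np.all(np.diff(a) > 0)

    def test_collapse_and_saturation_limits(self):
        assert tube_law_area(-60.0, VESSEL) < 1e-3
        assert tube_law_area(200.0, VESSEL) < VESSEL.max_area + 1e-9

    @given(st.floats(-30, 10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_pressure_inverts_area(self, p):
        a = tube_law_area(p, VESSEL)
        assert tube_law_pressure(a, VESSEL) == pytest.approx(p, abs=1e-8)

    def test_unattainable_area_is_nan(self):
        assert np.isnan(tube_law_pressure(VESSEL.max_area * 1.01, VESSEL))
        assert np.isnan(tube_law_pressure(0.0, VESSEL))


class TestForward:
    def test_zero_transmural_returns_reference_area(self):
        v = replace(VESSEL, kappa=0.0)
        out = forward_areas(ForwardInputs(p_ijv=3.0, p_carotid=80.0,
                                          probe_force=3.0 / v.mmhg_per_newton, vessel=v))
        assert out["ijv_area"] == pytest.approx(v.a_ref)

    def test_large_force_occludes(self):
        out = forward_areas(ForwardInputs(5.0, 80.0, 50.0, VESSEL))
        assert out["ijv_area"] < 0.5

    def test_kappa_zero_decouples_carotid(self):
        v = replace(VESSEL, kappa=0.0)
        a1 = forward_areas(ForwardInputs(5.0, 70.0, 2.0, v))["ijv_area"]
        a2 = forward_areas(ForwardInputs(5.0, 120.0, 2.0, v))["ijv_area"]
        assert a1 == a2

    def test_monotone_in_pressure_and_force(self):
        ps = np.linspace(-3, 15, 30)
        areas = [forward_areas(ForwardInputs(p, 80.0, 3.0, VESSEL))["ijv_area"] for p in ps]
        assert np.all(np.diff(areas) > 0)
        fs = np.linspace(0, 12, 30)
        areas_f = [forward_areas(ForwardInputs(5.0, 80.0, f, VESSEL))["ijv_area"] for f in fs]
        assert np.all(np.diff(areas_f) < 0)

    def test_carotid_linear_compliance(self):
        out_lo = forward_areas(ForwardInputs(5.0, 70.0, 2.0, VESSEL))
        out_hi = forward_areas(ForwardInputs(5.0, 110.0, 2.0, VESSEL))
        dA = out_hi["carotid_area"] - out_lo["carotid_area"]
        assert dA == pytest.approx(VESSEL.carotid_compliance * 40.0)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            ForwardInputs(5.0, 80.0, -1.0, VESSEL)


class TestInvertFrame:
    def test_reference_area_zero_external_gives_zero_pressure(self):
        v = replace(VESSEL, kappa=0.0)
        p = invert_frame(v.a_ref, p_carotid=v.carotid_ref_pressure, probe_force=0.0, vessel=v)
        assert p == pytest.approx(0.0, abs=1e-6)

    def test_round_trip_many_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            v = replace(
                VESSEL,
                k_stiff=float(rng.uniform(0.5, 4.0)),
                kappa=float(rng.uniform(0.0, 0.1)),
            )
            p_true = float(rng.uniform(-3.0, 20.0))
            p_car = float(rng.uniform(60.0, 120.0))
            force = float(rng.uniform(0.0, 6.0))
            area = forward_areas(ForwardInputs(p_true, p_car, force, v))["ijv_area"]
            if area > 0.95 * v.max_area or area < 0.5:
                # saturation plateau / full occlusion: pressure is not
                # identifiable from area there
                continue
            p_rec = invert_frame(area, p_car, force, v)
            assert p_rec == pytest.approx(p_true, abs=1e-6)

    def test_unattainable_area_flags_unconverged(self):
        with pytest.raises(ValueError, match="unconverged frame"):
            invert_frame(VESSEL.max_area * 1.1, 80.0, 0.0, VESSEL)


class TestWaveformEstimation:
    def test_constant_area_yields_constant_waveform_at_anchor(self):
        n = 1000
        area = TimeSeries(0.0, 0.01, np.full(n, 40.0), "mm2")
        force = TimeSeries(0.0, 0.01, np.full(n, 3.0), "N")
        carotid = TimeSeries(0.0, 0.01, np.full(n, VESSEL.carotid_ref_pressure), "mmHg")
        res = estimate_cvp_waveform(area, force, carotid, anchor_cvp=4.0, vessel=VESSEL)
        assert np.ptp(res.cvp_waveform.values) < 1e-6
        assert res.cvp_waveform.mean() == pytest.approx(4.0, abs=1e-6)

    def test_round_trip_recovers_true_waveform(self, default_capture):
        area, force, carotid = hold_window(default_capture)
        sl = default_capture.phase_slice("hold")
        true = default_capture.true_cvp.values[sl]
        anchor = float(np.mean(true))
        res = estimate_cvp_waveform(area, force, carotid, anchor, default_capture.vessel)
        rmse = np.sqrt(np.mean((res.cvp_waveform.values - true) ** 2))
        assert rmse < 0.05 * np.ptp(true)
        assert res.cvp_waveform.mean() == pytest.approx(anchor, abs=0.1)
        assert res.k_stiff_calibrated == pytest.approx(default_capture.vessel.k_stiff, rel=0.05)

    def test_carotid_coupling_restores_v_peak(self, default_capture):
        """Inverting with the carotid coupling on recovers the true v-over-a
        prominence; ignoring the coupling (kappa=0) under-reads the v peak,
        because the carotid's systolic push makes the vein look smaller
        exactly when the v wave occurs."""
        area, force, carotid = hold_window(default_capture)
        sl = default_capture.phase_slice("hold")
        true = default_capture.true_cvp.values[sl]
        anchor = float(np.mean(true))
        res_on = estimate_cvp_waveform(area, force, carotid, anchor, default_capture.vessel)
        res_off = estimate_cvp_waveform(
            area, force, carotid, anchor, replace(default_capture.vessel, kappa=0.0)
        )

        period = 60.0 / 75.0
        phase = (area.t / period) % 1.0
        v_mask = np.abs(phase - COMPONENT_PHASE["v"]) < 0.05
        a_mask = np.abs(phase - COMPONENT_PHASE["a"]) < 0.05

        def v_minus_a(wave):
            vals = wave.values - wave.mean()
            return float(np.mean(vals[v_mask]) - np.mean(vals[a_mask]))

        assert v_minus_a(res_on.cvp_waveform) > v_minus_a(res_off.cvp_waveform)
        assert v_minus_a(res_on.cvp_waveform) == pytest.approx(v_minus_a(
            TimeSeries(area.t0, area.dt, true)), abs=0.15)

    def test_noise_dampens_recovered_amplitude(self):
        from qcucvp import CaptureProtocol

        noisy = synth_capture(
            5.0, VesselParams(), protocol=CaptureProtocol(area_noise_sd=1.0), seed=3
        )
        sl = noisy.phase_slice("hold")
        true = noisy.true_cvp.values[sl]
        anchor = float(np.mean(true))
        area, force, carotid = hold_window(noisy)
        res = estimate_cvp_waveform(area, force, carotid, anchor, noisy.vessel)
        assert np.ptp(res.cvp_waveform.values) <= np.ptp(true)

    def test_excess_unconverged_frames_fail(self):
        n = 1000
        values = np.full(n, 40.0)
        values[: n // 2] = VESSEL.max_area * 1.2  # unattainable for half the hold
        area = TimeSeries(0.0, 0.01, values, "mm2")
        force = TimeSeries(0.0, 0.01, np.full(n, 3.0), "N")
        carotid = TimeSeries(0.0, 0.01, np.full(n, 80.0), "mmHg")
        with pytest.raises(ValueError, match="inverse solve failed"):
            estimate_cvp_waveform(area, force, carotid, 4.0, VESSEL)

    def test_few_unconverged_frames_interpolated(self):
        n = 1000
        values = np.full(n, 40.0)
        values[100:110] = VESSEL.max_area * 1.2
        area = TimeSeries(0.0, 0.01, values, "mm2")
        force = TimeSeries(0.0, 0.01, np.full(n, 3.0), "N")
        carotid = TimeSeries(0.0, 0.01, np.full(n, VESSEL.carotid_ref_pressure), "mmHg")
        res = estimate_cvp_waveform(area, force, carotid, 4.0, VESSEL, smooth_s=0.0)
        assert res.converged_frames == n - 10
        assert bool(res.unconverged_mask[105])
        assert np.all(np.isfinite(res.cvp_waveform.values))

    def test_frame_misalignment_rejected(self):
        area = TimeSeries(0.0, 0.01, np.full(500, 40.0), "mm2")
        force = TimeSeries(0.0, 0.01, np.full(400, 3.0), "N")
        carotid = TimeSeries(0.0, 0.01, np.full(500, 80.0), "mmHg")
        with pytest.raises(ValueError, match="frame-aligned"):
            estimate_cvp_waveform(area, force, carotid, 4.0, VESSEL)
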