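"""Smoothing, baseline correction, transit-time landmarks and PWV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pwvkit as pk
from pwvkit.errors import AnalysisError, ParameterError, UndefinedPWVError

from .conftest import xcorr_delay_frames

AUTO = pk.BaselineSpec(mode="automatic")


def shifted_pair(curve, m_frames, delta_d=60.0, scale=1.0):
    desc = curve.with_values(scale * np.roll(curve.values, m_frames))
    return pk.CurvePair(ascending=curve, descending=desc, delta_d_mm=delta_d)


class TestSmoothing:
    def test_constant_curve_unchanged(self):
        curve = pk.SampledCurve(np.full(64, 3.3), 500.0)
        out = pk.smooth_curve(curve, pk.SmoothingSpec(sigma_cycle_fraction=0.1))
        np.testing.assert_allclose(out.values, 3.3, atol=1e-12)

    def test_mean_conserved(self, neonate_curve):
        out = pk.smooth_curve(neonate_curve, pk.SmoothingSpec())
        assert out.values.mean() == pytest.approx(neonate_curve.values.mean(), abs=1e-10)

    def test_disabled_is_identity(self, neonate_curve):
        out = pk.smooth_curve(neonate_curve, pk.SmoothingSpec(enabled=False))
        assert out is neonate_curve

    @pytest.mark.parametrize("j", [0, 13, 99])
    def test_impulse_response_centered_and_symmetric(self, j):
        values = np.zeros(100)
        values[j] = 1.0
        out = pk.smooth_curve(pk.SampledCurve(values, 800.0),
                              pk.SmoothingSpec(sigma_cycle_fraction=0.02))
        assert int(np.argmax(out.values)) == j
        rolled = np.roll(out.values, -j)         # symmetric about j circularly
        np.testing.assert_allclose(rolled[1:], rolled[1:][::-1], atol=1e-12)


class TestBaseline:
    def test_constant_offset_removed(self, neonate_curve):
        shifted = neonate_curve.with_values(neonate_curve.values + 7.0)
        out = pk.baseline_correct(shifted, AUTO)
        idx = [i for i in range(44) if 0.80 <= i / 44 < 0.95]
        assert out.values[idx].mean() == pytest.approx(0.0, abs=1e-12)

    def test_none_is_identity(self, neonate_curve):
        assert pk.baseline_correct(neonate_curve, pk.BaselineSpec(mode="none")) is neonate_curve

    def test_automatic_window_indices_n40(self):
        # oracle: enumerate indices i with 0.80 <= i/40 < 0.95 -> {32,...,37}
        expected = [i for i in range(40) if 0.80 <= i / 40 < 0.95]
        assert expected == [32, 33, 34, 35, 36, 37]
        values = np.zeros(40)
        values[expected] = 5.0                    # only window samples non-zero
        out = pk.baseline_correct(pk.SampledCurve(values, 700.0), AUTO)
        assert out.values[0] == pytest.approx(-5.0)
        assert out.values[expected].mean() == pytest.approx(0.0, abs=1e-12)

    def test_manual_window(self):
        values = np.arange(20, dtype=float)
        spec = pk.BaselineSpec(mode="manual", manual_window=(0.0, 0.25))
        out = pk.baseline_correct(pk.SampledCurve(values, 700.0), spec)
        assert out.values[:5].mean() == pytest.approx(0.0, abs=1e-12)

    def test_empty_window_raises(self):
        spec = pk.BaselineSpec(mode="manual", manual_window=(0.01, 0.05))
        with pytest.raises(AnalysisError):
            pk.baseline_correct(pk.SampledCurve(np.arange(8.0), 700.0), spec)

    def test_manual_requires_window(self):
        with pytest.raises(ParameterError):
            pk.BaselineSpec(mode="manual")


class TestTransitTime:
    @pytest.mark.parametrize("method", ["TTF", "max_upslope", "TTP"])
    @pytest.mark.parametrize("m", [3, 17, 40])
    def test_shifted_pair_recovers_shift(self, neonate_params, method, m):
        """Whole-frame circular delays are recovered within one frame and agree
        with the cross-correlation argmax oracle."""
        curve = pk.generate_waveform(neonate_params, 256)
        pair = shifted_pair(curve, m)
        est = pk.transit_time(pair, method, AUTO)
        frame = curve.frame_duration_ms
        assert est.delta_t_ms == pytest.approx(m * frame, abs=frame)
        lag = xcorr_delay_frames(curve.values - curve.values.mean(),
                                 pair.descending.values - pair.descending.values.mean())
        assert lag == m

    @pytest.mark.parametrize("method", ["TTF", "max_upslope", "TTP"])
    def test_identical_pair_flagged_undefined(self, neonate_curve, method):
        pair = shifted_pair(neonate_curve, 0)
        est = pk.transit_time(pair, method, AUTO)
        assert est.delta_t_ms == 0.0
        assert est.pwv_m_per_s is None and not est.pwv_defined

    @pytest.mark.parametrize("method", ["TTF", "max_upslope", "TTP"])
    @pytest.mark.parametrize("lam", [0.1, 3.0, 250.0])
    def test_scale_invariance(self, neonate_params, method, lam):
        curve = pk.generate_waveform(neonate_params, 200)
        pair = shifted_pair(curve, 11)
        scaled = pk.CurvePair(
            ascending=curve.with_values(lam * pair.ascending.values),
            descending=pair.descending.with_values(lam * pair.descending.values),
            delta_d_mm=60.0)
        a = pk.transit_time(pair, method, AUTO)
        b = pk.transit_time(scaled, method, AUTO)
        assert b.delta_t_ms == pytest.approx(a.delta_t_ms, abs=1e-9)

    def test_baseline_only_applies_to_ttf(self, neonate_curve):
        pair = shifted_pair(neonate_curve, 5)
        est = pk.transit_time(pair, "TTP", AUTO)
        assert est.baseline.mode == "none"

    def test_automatic_and_manual_agree_on_flat_baseline(self):
        """Both corrections subtract the same (zero) offset when the curve is
        exactly baseline-flat in both windows (no dicrotic wave; the manual
        late-diastolic window sits beyond the smoothing kernel's reach)."""
        params = pk.default_params("neonate", dicrotic_amplitude_fraction=0.0)
        curve = pk.generate_waveform(params, 400)
        pair = shifted_pair(curve, 20)
        manual = pk.BaselineSpec(mode="manual", manual_window=(0.70, 0.78))
        a = pk.transit_time(pair, "TTF", AUTO)
        b = pk.transit_time(pair, "TTF", manual)
        assert a.delta_t_ms == pytest.approx(b.delta_t_ms, abs=1e-9)

    def test_flat_curve_raises_for_slope_methods(self):
        flat = pk.SampledCurve(np.full(64, 2.0), 500.0)
        pair = pk.CurvePair(ascending=flat, descending=flat, delta_d_mm=50.0)
        for method in ("TTF", "max_upslope"):
            with pytest.raises(AnalysisError):
                pk.transit_time(pair, method, AUTO)

    def test_negative_delta_t_reported_signed(self, neonate_params):
        curve = pk.generate_waveform(neonate_params, 256)
        pair = shifted_pair(curve, -10)           # descending landmark earlier
        est = pk.transit_time(pair, "TTP", AUTO)
        assert est.delta_t_ms < 0
        assert est.pwv_m_per_s < 0

    def test_unwrap_adds_one_cycle(self, neonate_params):
        curve = pk.generate_waveform(neonate_params, 256)
        late = curve.with_values(np.roll(curve.values, 150))
        pair = pk.CurvePair(ascending=late, descending=curve, delta_d_mm=60.0)
        raw = pk.transit_time(pair, "TTP", AUTO)
        assert raw.delta_t_ms < -curve.cycle_duration_ms / 2
        unwrapped = pk.transit_time(pair, "TTP", AUTO, unwrap=True)
        assert unwrapped.delta_t_ms == pytest.approx(
            raw.delta_t_ms + curve.cycle_duration_ms)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(m=st.integers(min_value=1, max_value=50),
           lam=st.floats(min_value=0.05, max_value=50.0),
           method=st.sampled_from(["TTF", "max_upslope", "TTP"]))
    def test_property_shift_and_scale(self, m, lam, method):
        """Δt equals the constructed shift and is invariant to common scaling."""
        curve = pk.generate_waveform(pk.default_params("neonate"), 256)
        pair = shifted_pair(curve, m, scale=lam)
        est = pk.transit_time(pair, method, AUTO)
        frame = curve.frame_duration_ms
        assert est.delta_t_ms == pytest.approx(m * frame, abs=frame)


class TestPwvArithmetic:
    @pytest.mark.parametrize("dd, dt, expected", [
        (60.0, 15.0, 4.0), (25.0, 12.5, 2.0), (150.0, -50.0, -3.0),
    ])
    def test_ratio(self, dd, dt, expected):
        assert pk.compute_pwv(dd, dt) == pytest.approx(expected)

    def test_zero_transit_time_raises(self):
        with pytest.raises(UndefinedPWVError):
            pk.compute_pwv(60.0, 0.0)


class TestTemporalResolution:
    @pytest.mark.parametrize("bpm, frames, exact, rounded", [
        (138, 44, 60000 / (138 * 44), 10),   # ~9.88 ms
        (138, 41, 60000 / (138 * 41), 11),   # ~10.60 ms
        (75, 39, 60000 / (75 * 39), 21),     # ~20.51 ms
        (60, 50, 20.0, 20),
    ])
    def test_values(self, bpm, frames, exact, rounded):
        assert pk.temporal_resolution_ms(bpm, frames) == pytest.approx(exact)
        assert pk.temporal_resolution_rounded_ms(bpm, frames) == rounded

    def test_strictly_decreasing_in_both_arguments(self):
        base = pk.temporal_resolution_ms(75, 35)
        assert pk.temporal_resolution_ms(76, 35) < base
        assert pk.temporal_resolution_ms(75, 36) < base

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            pk.temporal_resolution_ms(0, 40)
        with pytest.raises(ParameterError):
            pk.temporal_resolution_ms(75, 0)
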