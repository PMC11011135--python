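"""Normalization, gating and smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flexbeam import (
    GateWindow,
    RFChannelData,
    normalize_gated,
    normalize_global,
    smooth_delay_curve,
    smooth_trace,
)
from flexbeam.errors import DegenerateInputError, ValidationError
from flexbeam.preprocess import depth_to_sample

FS = 40e6
C = 1540.0


def _rf(data):
    return RFChannelData(data=np.asarray(data, dtype=float), fs=FS, sound_speed=C)


class TestNormalize:
    def test_global_scales_to_unit_peak(self, rng):
        data = rng.normal(size=(64, 4, 4)) * 5.0
        out = normalize_global(_rf(data))
        assert np.abs(out.data).max() == pytest.approx(1.0)
        np.testing.assert_allclose(out.data, data / np.abs(data).max())

    def test_global_idempotent_and_sign_preserving(self, rng):
        data = rng.normal(size=(32, 2, 2))
        once = normalize_global(_rf(data))
        twice = normalize_global(once)
        np.testing.assert_array_equal(once.data, twice.data)
        neg = normalize_global(_rf(-data))
        np.testing.assert_allclose(neg.data, -once.data)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normalize_global(_rf(np.zeros((16, 2, 2))))

    def test_gated_rescales_marker_band(self):
        # marker echo 0.2 at 15 mm, deep echo 1.0 at 60 mm
        n = depth_to_sample(np.array([15.0, 60.0]), FS, C)
        data = np.zeros((4000, 1, 1))
        data[n[0], 0, 0] = 0.2
        data[n[1], 0, 0] = 1.0
        out = normalize_gated(_rf(data), GateWindow(9.0, 24.0))
        assert out.data[n[0], 0, 0] == pytest.approx(1.0)
        assert out.data[n[1], 0, 0] == pytest.approx(5.0)

    def test_gate_covering_whole_record_equals_global(self, rng):
        data = rng.normal(size=(200, 2, 2))
        rf = _rf(data)
        gate = GateWindow(0.0, 1000.0)
        np.testing.assert_array_equal(
            normalize_gated(rf, gate).data, normalize_global(rf).data
        )

    def test_gated_peak_of_simulated_marker_is_one(self, rf_marker32):
        out = normalize_gated(normalize_global(rf_marker32), GateWindow(9.0, 24.0))
        sl = GateWindow(9.0, 24.0).sample_slice(out)
        assert np.abs(out.data[sl]).max() == pytest.approx(1.0)

    def test_normalization_never_moves_the_peak(self, rng):
        data = rng.normal(size=(300, 3, 3))
        rf = _rf(data)
        out = normalize_gated(normalize_global(rf), GateWindow(2.0, 4.0))
        for e in range(3):
            for s in range(3):
                assert np.argmax(np.abs(out.data[:, e, s])) == np.argmax(
                    np.abs(data[:, e, s])
                )

    def test_gate_validation(self):
        with pytest.raises(ValidationError):
            GateWindow(10.0, 9.0)
        with pytest.raises(ValidationError):
            GateWindow(100.0, 200.0).sample_slice(_rf(np.ones((10, 1, 1))))


class TestSmoothTrace:
    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(smooth_trace(x, window=1), x)

    def test_constant_trace_unchanged(self):
        x = np.full(40, 3.7)
        np.testing.assert_allclose(smooth_trace(x, window=9), x)

    def test_impulse_becomes_plateau(self):
        x = np.zeros(51)
        x[25] = 1.0
        out = smooth_trace(x, window=5)
        np.testing.assert_allclose(out[23:28], 0.2)
        assert out[20] == 0.0

    @pytest.mark.parametrize("window", [0, 2, 8, 99])
    def test_bad_windows_rejected(self, window):
        with pytest.raises(ValidationError):
            smooth_trace(np.zeros(20), window=window)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_linearity(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=60), r.normal(size=60)
        for method in ("moving_average", "savgol"):
            np.testing.assert_allclose(
                smooth_trace(a + 2 * b, method, 7),
                smooth_trace(a, method, 7) + 2 * smooth_trace(b, method, 7),
                atol=1e-12,
            )


class TestSmoothDelayCurve:
    def test_polynomials_pass_through(self):
        s = np.arange(64, dtype=float)
        for curve in (np.full(64, 5.0), 3.0 - 0.5 * s, 0.01 * s**2 + s):
            np.testing.assert_allclose(smooth_delay_curve(curve), curve, atol=1e-8)

    def test_spike_strongly_attenuated(self):
        curve = np.zeros(128)
        curve[60] = 10.0
        out = smooth_delay_curve(curve, window=21, order=2)
        # quadratic fit over 21 points leaves at most (order+1)/window of a spike
        assert abs(out[60]) < 10.0 * 3 / 21
        np.testing.assert_allclose(out.sum(), 10.0, atol=1e-8)  # mass preserved

    def test_even_window_made_odd(self):
        curve = np.arange(40, dtype=float)
        np.testing.assert_allclose(smooth_delay_curve(curve, window=20), curve, atol=1e-8)

    def test_short_curve_rejected(self):
        with pytest.raises(ValidationError):
            smooth_delay_curve(np.zeros(10), window=21)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_linearity(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=64), r.normal(size=64)
        np.testing.assert_allclose(
            smooth_delay_curve(a + 3 * b),
            smooth_delay_curve(a) + 3 * smooth_delay_curve(b),
            atol=1e-10,
        )
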