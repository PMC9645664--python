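"""Signal processing and kinematic metric extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reachadapt import kinematics as km
from reachadapt.schedule import TrialSpec


def _make_trial(x, y, fs=1000.0, **kw):
    n = len(x)
    return km.KinematicTrial(
        fs=fs, x=np.asarray(x, float), y=np.asarray(y, float),
        fx=np.zeros(n), fy=np.zeros(n), **kw,
    )


def _straight_reach(fs=1000.0, v=0.5, d=0.15, pre=50):
    """Constant-speed straight reach along +y after a stationary hold."""
    n_move = int(d / v * fs) + 1
    y = np.concatenate([np.zeros(pre), np.arange(n_move) * v / fs])
    x = np.zeros_like(y)
    return _make_trial(x, y, fs)


class TestLowpass:
    def test_dc_gain_unity(self):
        out = km.lowpass(np.full(2000, 3.7))
        np.testing.assert_allclose(out[100:-100], 3.7, atol=1e-9)

    def test_passband_and_stopband_match_butterworth_response(self):
        """Dual-pass gain follows the squared analytic magnitude response."""
        fs, n = 1000.0, 4000
        t = np.arange(n) / fs
        for f0 in (10.0, 200.0):
            sig = np.sin(2 * np.pi * f0 * t)
            out = km.lowpass(sig, fs=fs)
            measured = out[1000:3000].std() / sig[1000:3000].std()
            analytic = (1.0 / np.sqrt(1.0 + (f0 / 50.0) ** 8)) ** 2
            assert measured == pytest.approx(analytic, rel=0.01, abs=1e-4)

    def test_zero_phase_time_reversal_symmetry(self, rng):
        sig = rng.standard_normal(500)
        fwd = km.lowpass(sig)
        rev = km.lowpass(sig[::-1])[::-1]
        np.testing.assert_allclose(fwd, rev, atol=1e-8)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            km.lowpass(np.zeros(100), fs=80.0, fc=50.0)


class TestDifferentiate:
    def test_linear_ramp_exact(self):
        p = 0.25 * np.arange(100) / 1000.0
        v = km.differentiate(p, fs=1000.0)
        np.testing.assert_allclose(v, 0.25, atol=1e-9)

    def test_quartic_exact_at_interior(self):
        """4th-order stencil is exact for 4th-degree polynomials."""
        fs = 100.0
        t = np.arange(50) / fs
        coeffs = [0.3, -1.2, 2.0, 0.5, -0.7]
        p = np.polyval(coeffs, t)
        dp = np.polyval(np.polyder(coeffs), t)
        v = km.differentiate(p, fs=fs)
        np.testing.assert_allclose(v[2:-2], dp[2:-2], atol=1e-10)

    def test_constant_series_zero(self):
        v = km.differentiate(np.full(20, 1.23), fs=1000.0)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            km.differentiate(np.zeros(4), fs=1000.0)


class TestOnsetAndAngle:
    def test_stationary_trial_has_no_onset(self):
        tr = _make_trial(np.zeros(100), np.zeros(100))
        with pytest.raises(km.NoOnsetError):
            km.reach_onset(tr)

    def test_onset_index_matches_closed_form(self):
        v, r, fs = 0.5, 0.005, 1000.0
        tr = _straight_reach(fs=fs, v=v, pre=0)
        onset = km.reach_onset(tr, start_radius=r)
        assert onset == int(np.floor(r / v * fs)) + 1

    def test_onset_is_position_only(self):
        tr = _straight_reach()
        tr2 = km.KinematicTrial(
            fs=tr.fs, x=tr.x, y=tr.y, fx=tr.fx - 4.0, fy=tr.fy, spec=None
        )
        assert km.reach_onset(tr) == km.reach_onset(tr2)

    def test_straight_reach_zero_angle(self):
        assert km.initial_angle(_straight_reach()) == pytest.approx(0.0, abs=1e-9)

    def test_ten_degree_crossing(self):
        """A path crossing y = 5 cm at x = -0.05 tan(10 deg) reads +10 deg."""
        fs = 1000.0
        y = np.concatenate([np.zeros(20), np.linspace(0, 0.15, 600)])
        x = -np.tan(np.radians(10.0)) * y
        tr = _make_trial(x, y, fs)
        assert km.initial_angle(tr, reach_distance=0.15) == pytest.approx(10.0, abs=1e-6)

    def test_mirrored_trajectory_negates_angle(self, rng):
        y = np.concatenate([np.zeros(20), np.linspace(0, 0.15, 600)])
        x = 0.02 * np.sin(np.linspace(0, np.pi, y.size)) + 0.001
        a = km.initial_angle(_make_trial(x, y))
        b = km.initial_angle(_make_trial(-x, y))
        assert a == pytest.approx(-b, abs=1e-9)

    def test_angle_invariant_to_resampling(self):
        """The initial angle is a path property: uniform temporal
        resampling leaves it unchanged."""
        y = np.concatenate([np.zeros(40), np.linspace(0, 0.15, 1200)])
        x = -0.03 * np.sin(np.linspace(0, np.pi, y.size))
        a1 = km.initial_angle(_make_trial(x, y, fs=1000.0))
        a2 = km.initial_angle(_make_trial(x[::4], y[::4], fs=250.0))
        assert a1 == pytest.approx(a2, abs=0.05)

    def test_no_crossing_error(self):
        y = np.concatenate([np.zeros(10), np.linspace(0, 0.02, 100)])
        with pytest.raises(km.NoCrossingError):
            km.initial_angle(_make_trial(np.zeros_like(y), y))


class TestPathLength:
    def test_straight_reach_length(self):
        tr = _straight_reach(v=0.5)
        pl = km.path_length(tr, prefiltered=True)
        assert pl == pytest.approx(0.15, abs=1e-3)

    def test_semicircle_arc_length(self):
        """A semicircular detour of radius r has length pi * r."""
        fs, r = 1000.0, 0.05
        phi = np.linspace(0, np.pi, 500)
        x = r * np.sin(phi)
        y = r * (1 - np.cos(phi))
        x = np.concatenate([np.zeros(10), x])
        y = np.concatenate([np.zeros(10), y])
        tr = _make_trial(x, y, fs)
        pl = km.path_length(tr, t_max=0.6, prefiltered=True)
        assert pl == pytest.approx(np.pi * r, abs=1e-3)

    def test_stationary_after_onset(self):
        """A hand that barely exits the start target and freezes adds no
        further path: the integral equals the distance travelled."""
        y = np.concatenate([np.zeros(10), np.linspace(0, 0.006, 20), np.full(700, 0.006)])
        tr = _make_trial(np.zeros_like(y), y)
        pl = km.path_length(tr, prefiltered=True)
        assert pl == pytest.approx(0.006, abs=1e-3)


class TestForwardVelocity:
    def test_constant_speed_value(self):
        tr = _straight_reach(v=0.5)
        assert km.forward_velocity_at_threshold(tr, prefiltered=True) == pytest.approx(
            0.5, rel=1e-3
        )

    def test_time_dilation_halves_velocity(self):
        y = np.concatenate([np.zeros(20), np.linspace(0, 0.15, 300)])
        tr1 = _make_trial(np.zeros_like(y), y, fs=1000.0)
        y2 = np.repeat(y, 2)
        tr2 = _make_trial(np.zeros_like(y2), y2, fs=1000.0)
        v1 = km.forward_velocity_at_threshold(tr1, prefiltered=True)
        v2 = km.forward_velocity_at_threshold(tr2, prefiltered=True)
        assert v2 == pytest.approx(v1 / 2, rel=0.02)

    def test_mirroring_preserves_forward_velocity(self):
        y = np.concatenate([np.zeros(20), np.linspace(0, 0.15, 300)])
        x = -0.02 * np.sin(np.linspace(0, np.pi, y.size))
        v1 = km.forward_velocity_at_threshold(_make_trial(x, y), prefiltered=True)
        v2 = km.forward_velocity_at_threshold(_make_trial(-x, y), prefiltered=True)
        assert v1 == pytest.approx(v2, abs=1e-12)


def test_full_pipeline_on_noisy_straight_reach(rng):
    """Filtering + differentiation recover clean metrics from noisy data."""
    tr = _straight_reach(v=0.5)
    noisy = km.KinematicTrial(
        fs=tr.fs,
        x=tr.x + 2e-4 * rng.standard_normal(tr.x.size),
        y=tr.y + 2e-4 * rng.standard_normal(tr.y.size),
        fx=tr.fx,
        fy=tr.fy,
    )
    m = km.trial_metrics(noisy)
    assert abs(m.initial_angle) < 1.0
    assert m.path_length == pytest.approx(0.15, abs=5e-3)
    assert m.threshold_crossing_time > 0


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    amp=st.floats(-0.04, 0.04, allow_nan=False),
    bias=st.floats(-0.01, 0.01, allow_nan=False),
)
def test_initial_angle_odd_under_mirroring(amp, bias):
    """For any lateral profile, mirroring the trajectory negates the
    initial angle (odd symmetry of the sign convention)."""
    y = np.concatenate([np.zeros(20), np.linspace(0, 0.15, 400)])
    x = amp * np.sin(np.linspace(0, np.pi, y.size)) + bias * y / 0.15
    a = km.initial_angle(_make_trial(x, y))
    b = km.initial_angle(_make_trial(-x, y))
    assert a == pytest.approx(-b, abs=1e-9)


def test_pool_angles_across_directions():
    cw = -np.array([10.0, 8.0, 6.0])
    ccw = np.array([9.0, 7.0, 5.0])
    angles = np.concatenate([cw, ccw])
    groups = np.array(["cw"] * 3 + ["ccw"] * 3)
    pooled = km.pool_angles_across_directions(angles, groups)
    assert (pooled > 0).all()
    np.testing.assert_allclose(pooled[:3], -cw)
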