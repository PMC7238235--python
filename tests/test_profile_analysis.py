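"""Dwell-window detection, residual velocity, compression time, prolongation."""

import numpy as np
import pytest
from scipy import stats

import tabscale as ts
from tabscale.profile_analysis import (
    compression_time,
    detect_dwell_window,
    prolongation,
    residual_dwell_velocity,
    residual_dwell_velocity_fit,
    summarize,
)
from tabscale.profiles import CompactionProfile, ProfileError
from tabscale.synthetic_data import CsDeviationModel, generate_profile_pair


def flat_profile(sep_values, dt=0.1, stress=None):
    t = np.arange(len(sep_values)) * dt
    sep = np.asarray(sep_values, dtype=float)
    return CompactionProfile(t, sep / 2, -sep / 2, stress)


class TestDwellWindow:
    def test_simulated_profile_recovers_closed_form_dwell(self, xl100):
        profile = ts.simulate_displacement(xl100.press, 40.0, 3.0, sampling_step=0.05)
        window = detect_dwell_window(profile, separation_tolerance=1e-9)
        width = window.length + profile.dt
        assert width == pytest.approx(ts.dwell_time(xl100.press, 40.0), abs=0.05)
        assert not window.degenerate

    def test_monotone_ramp_flagged_degenerate(self):
        profile = flat_profile(np.linspace(5.0, 2.0, 50))
        window = detect_dwell_window(profile, separation_tolerance=1e-9)
        assert window.degenerate
        assert window.length == 0.0

    def test_huge_tolerance_returns_whole_profile(self):
        sep = 2.0 + np.abs(np.linspace(-1.0, 1.0, 40))
        profile = flat_profile(sep)
        window = detect_dwell_window(profile, separation_tolerance=10.0)
        assert window.t_start == profile.time[0]
        assert window.t_end == profile.time[-1]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ProfileError, match="10 samples"):
            detect_dwell_window(flat_profile([2.0] * 5))


class TestResidualVelocity:
    def test_constant_separation_gives_zero(self):
        profile = flat_profile([2.0] * 100)
        window = detect_dwell_window(profile, 1e-6)
        assert residual_dwell_velocity(profile, window) == pytest.approx(0.0, abs=1e-12)

    def test_known_linear_approach(self):
        # 10 um decrease over 20 ms -> -0.5 mm/s
        t = np.arange(0.0, 20.05, 0.1)
        sep = 2.0 - 0.010 * t / 20.0
        profile = CompactionProfile(t, sep / 2, -sep / 2)
        window = detect_dwell_window(profile, separation_tolerance=1.0)
        assert residual_dwell_velocity(profile, window) == pytest.approx(-0.5, rel=1e-9)

    def test_invariant_under_offset_and_time_shift(self):
        t = np.arange(0.0, 20.05, 0.1)
        sep = 2.0 - 0.010 * t / 20.0
        a = CompactionProfile(t, sep / 2, -sep / 2)
        b = CompactionProfile(t + 500.0, (sep + 3.0) / 2, -(sep + 3.0) / 2)
        wa = detect_dwell_window(a, 1.0)
        wb = detect_dwell_window(b, 1.0)
        assert residual_dwell_velocity(a, wa) == pytest.approx(
            residual_dwell_velocity(b, wb), rel=1e-9, abs=1e-12
        )

    def test_noisy_slope_recovery_within_fit_ci(self):
        # noisy linear approach: true slope inside the 95% CI in >=90% of reps
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 20.0, 0.1)
        true_v = -0.5  # mm/s
        hits = 0
        reps = 500
        for _ in range(reps):
            sep = 2.0 + true_v / 1000.0 * t + rng.normal(0, 0.002, t.size)
            profile = CompactionProfile(t, sep / 2, -sep / 2)
            window = detect_dwell_window(profile, separation_tolerance=10.0)
            fit = residual_dwell_velocity_fit(profile, window)
            half = stats.t.ppf(0.975, fit.n_samples - 2) * fit.stderr
            if abs(fit.velocity - true_v) <= half:
                hits += 1
        assert hits / reps >= 0.90

    def test_too_few_samples_in_window_rejected(self):
        profile = flat_profile([2.0] * 20)
        from tabscale.profile_analysis import DwellWindow

        with pytest.raises(ProfileError, match="at least 3"):
            residual_dwell_velocity(profile, DwellWindow(0.0, 0.1, False))


class TestCompressionTime:
    def test_triangular_pulse_half_threshold(self):
        t = np.arange(0.0, 60.0, 0.1)
        stress = np.maximum(0.0, 100.0 * (1 - np.abs(t - 30.0) / 20.0))  # base 40 ms
        profile = flat_profile(np.full(t.size, 2.0), dt=0.1, stress=stress)
        assert compression_time(profile, 0.5) == pytest.approx(20.0, abs=1e-9)

    def test_small_threshold_approaches_full_pulse(self):
        t = np.arange(0.0, 60.0, 0.1)
        stress = np.maximum(0.0, 100.0 * (1 - np.abs(t - 30.0) / 20.0))
        profile = flat_profile(np.full(t.size, 2.0), dt=0.1, stress=stress)
        assert compression_time(profile, 1e-9) == pytest.approx(40.0, abs=0.01)

    def test_all_zero_stress_errors(self):
        profile = flat_profile([2.0] * 30, stress=np.zeros(30))
        with pytest.raises(ProfileError, match="all-zero"):
            compression_time(profile)

    def test_missing_stress_channel_errors(self):
        with pytest.raises(ProfileError, match="no stress"):
            compression_time(flat_profile([2.0] * 30))


class TestProlongation:
    def test_identical_profiles_give_exact_zero(self):
        t = np.arange(0.0, 60.0, 0.1)
        stress = np.maximum(0.0, 100.0 * (1 - np.abs(t - 30.0) / 20.0))
        profile = flat_profile(np.full(t.size, 2.0), stress=stress)
        assert prolongation(profile, profile) == 0.0

    def test_time_stretched_pair_recovers_stretch(self):
        t = np.arange(0.0, 60.0, 0.1)
        stress = np.maximum(0.0, 100.0 * (1 - np.abs(t - 30.0) / 20.0))
        press = flat_profile(np.full(t.size, 2.0), stress=stress)
        t2 = np.arange(0.0, 72.0, 0.1)
        stress2 = np.interp(t2 / 1.2, t, stress)
        cs = flat_profile(np.full(t2.size, 2.0), stress=stress2)
        assert prolongation(cs, press) == pytest.approx(0.20, abs=1e-3)
        # antisymmetric sign for stretched pairs
        assert np.sign(prolongation(press, cs)) == -np.sign(prolongation(cs, press))

    def test_synthetic_grid_bounded_and_ordered(self, xl100):
        values = {}
        for stress in (50.0, 300.0):
            for nt in (20.0, 60.0):
                op = ts.OperatingPoint(
                    turret_frequency=nt, paddle_frequency=0.0,
                    target_stress=stress, tablet_weight=725e-6,
                )
                rot, cs = generate_profile_pair(xl100.press, op)
                values[(stress, nt)] = prolongation(cs, rot)
        assert max(values.values()) <= 0.20
        assert values[(300.0, 20.0)] > values[(50.0, 20.0)]  # enhanced at high stress
        assert values[(300.0, 20.0)] > values[(300.0, 60.0)]  # reduced at high speed

    def test_residual_velocity_magnitude_grows_as_dwell_shrinks(self, xl100, xl400):
        # across machine scales/speeds: shorter dwell -> faster residual approach
        results = []
        for press, nt in ((xl100.press, 20.0), (xl100.press, 60.0), (xl400.press, 60.0)):
            op = ts.OperatingPoint(
                turret_frequency=nt, paddle_frequency=0.0,
                target_stress=150.0, tablet_weight=725e-6,
            )
            _, cs = generate_profile_pair(xl100.press if press is None else press, op)
            dwell = cs.meta["dwell_ms"] * cs.meta["time_stretch"]
            mid = cs.time[cs.time.size // 2]
            sel = (cs.time > mid - 0.35 * dwell) & (cs.time < mid + 0.35 * dwell)
            fit = stats.linregress(cs.time[sel], cs.separation[sel])
            results.append((dwell, abs(fit.slope * 1000.0)))
        results.sort(key=lambda r: r[0])
        speeds = [v for _, v in results]
        assert speeds == sorted(speeds, reverse=True)


def test_summarize_assembles_metrics(xl100):
    fx = xl100
    op = ts.OperatingPoint(
        turret_frequency=20.0, paddle_frequency=0.0, target_stress=150.0,
        tablet_weight=725e-6,
    )
    rot, cs = generate_profile_pair(fx.press, op)
    metrics = summarize(cs, reference=rot)
    assert metrics.peak_stress == pytest.approx(150.0)
    assert metrics.prolongation_vs_reference > 0
    assert metrics.compression_time >= metrics.dwell_time
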