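"""Coordination metrics: correlation, peaks, relative phase, energy,
episode summaries, windowed correlation and transition detection."""

import numpy as np
import pytest

from posturecoord import metrics, synthetic
from posturecoord.metrics import (DegenerateSeriesError, NoTransition,
                                  pearson_correlation, cycle_peaks,
                                  relative_phase, energy_cost,
                                  summarize_episode, windowed_correlation,
                                  transition_frequency)
from posturecoord.synthetic import FixtureSpec, gen_coordination_pair
from posturecoord.task import TaskSpec


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x) == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, -x + 7) == pytest.approx(-1.0)

    def test_orthogonal_sinusoids(self):
        t = np.linspace(0, 4, 40_000, endpoint=False)
        assert pearson_correlation(np.sin(2 * np.pi * t),
                                   np.cos(2 * np.pi * t)) == pytest.approx(0.0, abs=1e-3)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=100), rng.normal(size=100)
        r = pearson_correlation(x, y)
        assert pearson_correlation(y, x) == pytest.approx(r)
        assert pearson_correlation(3 * x + 1, y) == pytest.approx(r)
        assert pearson_correlation(-2 * x, y) == pytest.approx(-r)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateSeriesError):
            pearson_correlation(np.ones(10), np.arange(10.0))
        with pytest.raises(DegenerateSeriesError):
            pearson_correlation([1.0, 2.0], [3.0, 4.0])


class TestCyclePeaks:
    def test_known_sine_maxima(self):
        f = 0.5
        t = np.arange(0, 10, 1 / 60)
        peaks, skipped = cycle_peaks(np.sin(2 * np.pi * f * t), t, f)
        assert skipped == 0
        expected = 0.5 + 2.0 * np.arange(len(peaks))
        assert np.allclose(peaks, expected, atol=1 / 60)

    def test_shift_equivariance(self):
        f = 0.4
        t = np.arange(0, 15, 1 / 60)
        y = np.sin(2 * np.pi * f * t)
        p0, _ = cycle_peaks(y, t, f)
        delta = 0.3
        p1, _ = cycle_peaks(np.sin(2 * np.pi * f * (t - delta)), t, f)
        # interior peaks all move by delta
        assert np.allclose(p1[1:-1] - p0[1:-1], delta, atol=1.5 / 60)

    def test_noisy_sinusoid_recovery(self):
        f = 0.5
        rng = np.random.default_rng(2)
        t = np.arange(0, 20, 1 / 60)
        y = np.sin(2 * np.pi * f * t) + rng.normal(0, 0.05, t.shape)
        peaks, _ = cycle_peaks(y, t, f)
        expected = 0.5 + 2.0 * np.arange(len(peaks))
        assert np.all(np.abs(peaks - expected) < 0.02 / f)

    def test_too_short_series(self):
        t = np.arange(0, 1.0, 1 / 60)
        with pytest.raises(ValueError):
            cycle_peaks(np.sin(t), t, 0.5)


class TestRelativePhase:
    def test_synchronous_peaks(self):
        assert relative_phase(1.0, 1.0, 0.5) == 0.0

    def test_printed_formula_arithmetic(self):
        assert relative_phase(1.0, 0.5, 1.0) == pytest.approx(np.pi / 2)

    def test_nonnegative(self):
        assert relative_phase(0.2, 0.9, 0.5) >= 0

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            relative_phase(0.0, 1.0, 0.0)


class TestEnergyCost:
    def test_constant_arithmetic(self):
        n = 6000   # 100 s at 60 Hz
        tau = np.full(n, 10.0)
        om = np.full(n, 0.5)
        assert energy_cost(tau, om, 100.0 / n) == pytest.approx(500.0)

    def test_zero_torque_contributes_nothing(self):
        tau = np.zeros(100)
        assert energy_cost(tau, np.ones(100), 0.01) == 0.0

    def test_bruteforce_and_sign_invariance(self):
        rng = np.random.default_rng(4)
        tau = rng.normal(size=(50, 2))
        om = rng.normal(size=(50, 2))
        brute = sum(abs(tau[i, j] * om[i, j]) * 0.02
                    for i in range(50) for j in range(2))
        assert energy_cost(tau, om, 0.02) == pytest.approx(brute, rel=1e-12)
        assert energy_cost(-tau, om, 0.02) == pytest.approx(brute, rel=1e-12)
        assert energy_cost(tau, -om, 0.02) == pytest.approx(brute, rel=1e-12)


class TestSummarizeEpisode:
    def test_in_phase_fixture(self):
        log = gen_coordination_pair(FixtureSpec(frequency=0.4, lag=0.0,
                                                duration=25, seed=0))
        s = summarize_episode(log, TaskSpec(amplitude_A=0.1, frequency_f=0.4))
        assert s.hip_ankle_correlation > 0.99
        assert s.mode_label == "in_phase"
        assert s.relative_phase == pytest.approx(0.0, abs=0.05)

    def test_anti_phase_fixture(self):
        half_period = 0.5 / 0.4
        log = gen_coordination_pair(FixtureSpec(frequency=0.4, lag=half_period,
                                                duration=25, seed=0))
        s = summarize_episode(log, TaskSpec(amplitude_A=0.1, frequency_f=0.4))
        assert s.hip_ankle_correlation < -0.99
        assert s.mode_label == "anti_phase"

    def test_mean_head_velocity_of_cosine_target_motion(self, params):
        # head following the target law with amplitude a: mean |dx/dt| = 4 f a
        f, a = 0.4, 0.05
        t = np.arange(0, 25, 1 / 60)
        import pandas as pd
        from posturecoord.task import LOG_COLUMNS, TrajectoryLog
        head = a * (1 - np.cos(2 * np.pi * f * t))
        head_v = np.gradient(head, 1 / 60)
        df = pd.DataFrame(0.0, index=np.arange(len(t)), columns=list(LOG_COLUMNS))
        df["time"] = t
        df["theta_ankle"] = np.sin(2 * np.pi * f * t) * 0.05
        df["theta_hip"] = np.sin(2 * np.pi * f * t) * 0.04
        df["head_x"] = head
        df["head_vx"] = head_v
        df["target_x"] = head
        df["fallen"] = False
        s = summarize_episode(TrajectoryLog(data=df), TaskSpec(amplitude_A=a, frequency_f=f))
        assert s.mean_head_velocity == pytest.approx(4 * f * a, abs=1e-3)
        assert s.head_amplitude == pytest.approx(a, rel=0.02)

    def test_fall_inside_window_rejected(self):
        log = gen_coordination_pair(FixtureSpec(frequency=0.4, duration=25, seed=0))
        log.data.loc[len(log.data) // 2, "fallen"] = True
        with pytest.raises(ValueError, match="fall"):
            summarize_episode(log, TaskSpec(amplitude_A=0.1, frequency_f=0.4))

    def test_parameter_recovery_grid(self):
        """Generator-as-oracle: lag and amplitudes recovered within stated
        tolerances over a seeded grid of fixtures with 5% noise."""
        f = 0.4
        period = 1 / f
        for i, lag in enumerate([0.0, 0.1, 0.25, 0.5, 1.0, 1.25]):
            spec = FixtureSpec(frequency=f, lag=lag, ankle_amplitude=0.06,
                               hip_amplitude=0.09, noise_sigma=0.05,
                               duration=40, seed=100 + i)
            s = summarize_episode(gen_coordination_pair(spec),
                                  TaskSpec(amplitude_A=0.1, frequency_f=f))
            expected_phase = min(lag, period - lag) * f * np.pi
            # correlation sign must match the construction
            if lag < 0.25 * period or lag > 0.75 * period:
                assert s.hip_ankle_correlation > 0
            elif 0.3 * period < lag < 0.7 * period:
                assert s.hip_ankle_correlation < 0
            assert s.relative_phase == pytest.approx(expected_phase,
                                                     rel=0.05, abs=0.02)
            assert s.peak_to_peak_ankle == pytest.approx(2 * 0.06, rel=0.03)
            assert s.peak_to_peak_hip == pytest.approx(2 * 0.09, rel=0.03)


class TestWindowedCorrelation:
    def test_globally_in_phase(self):
        log = gen_coordination_pair(FixtureSpec(frequency=0.4, duration=25, seed=1))
        t = log.data["time"].to_numpy()
        c, r = windowed_correlation(log.data["theta_ankle"], log.data["theta_hip"],
                                    t, window=300, stride=30)
        assert np.all(r > 0)
        assert len(c) == len(r)

    def test_single_window_consistency(self):
        log = gen_coordination_pair(FixtureSpec(frequency=0.4, duration=25, seed=1))
        a = log.data["theta_ankle"].to_numpy()
        h = log.data["theta_hip"].to_numpy()
        t = log.data["time"].to_numpy()
        _, r = windowed_correlation(a, h, t, window=len(a))
        assert len(r) == 1
        assert r[0] == pytest.approx(pearson_correlation(a, h))

    def test_sign_flip_crosses_zero_once(self):
        log = synthetic.gen_mode_switch_series(
            0.15, 0.036, 0.69, FixtureSpec(frequency=0.15, chirp_rate=0.036,
                                           duration=25, seed=3))
        c, r = windowed_correlation(log.data["theta_ankle"], log.data["theta_hip"],
                                    log.data["time"].to_numpy(), window=300,
                                    stride=30)
        signs = np.sign(r[np.abs(r) > 0.2])
        flips = np.sum(np.diff(signs) != 0)
        assert flips == 1

    def test_window_validation(self):
        with pytest.raises(ValueError):
            windowed_correlation(np.ones(50), np.ones(50), np.arange(50.0), window=5)


class TestTransitionFrequency:
    def test_linear_interpolation_example(self):
        got = transition_frequency([0.5, 0.1, -0.3], [0.4, 0.6, 0.8])
        assert got == pytest.approx(0.65)

    def test_all_positive_yields_no_transition(self):
        assert transition_frequency([0.5, 0.4, 0.2], [0.1, 0.2, 0.3]) == NoTransition()

    def test_chirp_fixture_recovery_including_reported_value(self):
        """Programmed flips (0.5 and the reported 0.69 Hz) are recovered
        within one window stride of chirp frequency."""
        window, stride = 300, 30
        rate, f0 = 0.036, 0.15
        stride_hz = rate * stride / 60.0
        window_hz = rate * window / 60.0
        for flip in (0.5, 0.69):
            log = synthetic.gen_mode_switch_series(
                f0, rate, flip, FixtureSpec(frequency=f0, chirp_rate=rate,
                                            duration=25, seed=8))
            c, r = windowed_correlation(log.data["theta_ankle"],
                                        log.data["theta_hip"],
                                        log.data["time"].to_numpy(),
                                        window=window, stride=stride)
            freqs = f0 + rate * c
            got = transition_frequency(r, freqs)
            assert not isinstance(got, NoTransition)
            assert abs(got - flip) <= window_hz / 2 + stride_hz

    def test_flip_below_start_no_crossing_from_positive(self):
        log = synthetic.gen_mode_switch_series(
            0.3, 0.036, 0.1, FixtureSpec(frequency=0.3, chirp_rate=0.036,
                                         duration=25, seed=9))
        c, r = windowed_correlation(log.data["theta_ankle"], log.data["theta_hip"],
                                    log.data["time"].to_numpy(), window=300,
                                    stride=30)
        # series is anti-phase from the start: no positive->negative crossing
        assert transition_frequency(r, 0.3 + 0.036 * c) == NoTransition()

    def test_flip_above_end_no_transition(self):
        log = synthetic.gen_mode_switch_series(
            0.15, 0.036, 5.0, FixtureSpec(frequency=0.15, chirp_rate=0.036,
                                          duration=25, seed=10))
        c, r = windowed_correlation(log.data["theta_ankle"], log.data["theta_hip"],
                                    log.data["time"].to_numpy(), window=300,
                                    stride=30)
        assert transition_frequency(r, 0.15 + 0.036 * c) == NoTransition()
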