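"""Spatiotemporal, symmetry, variability, phase and spectral features."""

import numpy as np
import pytest

import gaitpain as gp
from gaitpain.errors import ConfigError, InsufficientDataError, NoGaitError


def make_events(merged_times, toe_offs=False, swing_left=0.4, swing_right=0.4):
    """Alternating left/right heel strikes from a merged time vector."""
    merged_times = np.asarray(merged_times, dtype=float)
    left = merged_times[0::2]
    right = merged_times[1::2]
    kw = {}
    if toe_offs:
        kw = {"left_toe_offs": left[1:] - swing_left,
              "right_toe_offs": right[1:] - swing_right}
    return gp.GaitEventSeries(left, right, **kw)


class TestDetectGaitEvents:
    def test_recovers_generator_ground_truth(self, symmetric_trial):
        sig, ev_true = symmetric_trial
        det = gp.detect_gait_events(sig)
        t_true, _ = ev_true.merged_heel_strikes()
        t_det, _ = det.merged_heel_strikes()
        assert len(t_det) == len(t_true)
        assert np.max(np.abs(t_det - t_true)) < 0.05

    def test_constant_signal_raises_no_gait(self):
        sig = gp.RawGaitSignal(np.ones(1000), 100.0, 20.0)
        with pytest.raises(NoGaitError):
            gp.detect_gait_events(sig)

    def test_pure_2hz_sinusoid_yields_20_events(self):
        t = np.arange(0, 10, 0.01)
        sig = gp.RawGaitSignal(np.sin(2 * np.pi * 2.0 * t), 100.0, 20.0)
        det = gp.detect_gait_events(sig)
        assert det.n_steps == 20

    def test_short_trial_rejected(self):
        sig = gp.RawGaitSignal(np.random.default_rng(0).normal(size=200), 100.0, 20.0)
        with pytest.raises(InsufficientDataError):
            gp.detect_gait_events(sig)


class TestSpatiotemporal:
    def test_twenty_metres_in_16s_28_steps(self):
        """speed = d/t, step length = d/steps, cadence = steps per minute."""
        ev = make_events(np.linspace(0.0, 16.0, 28))
        sig = gp.RawGaitSignal(np.zeros(2000), 100.0, walk_distance=20.0)
        out = gp.spatiotemporal(ev, sig)
        assert out["gait_speed"] == pytest.approx(1.25)
        assert out["step_length"] == pytest.approx(0.714, abs=5e-4)
        assert out["cadence"] == pytest.approx(105.0)

    def test_equal_stance_and_swing_gives_50_50(self):
        # strides of 1.0 s per side; toe-off at the stride midpoint
        merged = np.arange(0.0, 10.0, 0.5)
        ev = make_events(merged, toe_offs=True, swing_left=0.5, swing_right=0.5)
        sig = gp.RawGaitSignal(np.zeros(2000), 100.0, walk_distance=12.0)
        out = gp.spatiotemporal(ev, sig)
        for side in ("left", "right"):
            assert out[f"stance_percent_{side}"] == pytest.approx(50.0, abs=1e-9)
            assert out[f"swing_percent_{side}"] == pytest.approx(50.0, abs=1e-9)

    def test_time_dilation_halves_speed_not_step_length(self):
        base = np.linspace(0.0, 16.0, 28)
        sig = gp.RawGaitSignal(np.zeros(4000), 100.0, walk_distance=20.0)
        out1 = gp.spatiotemporal(make_events(base), sig)
        out2 = gp.spatiotemporal(make_events(2 * base), sig)
        assert out2["gait_speed"] == pytest.approx(out1["gait_speed"] / 2)
        assert out2["step_length"] == pytest.approx(out1["step_length"])

    def test_too_few_strides_rejected(self):
        ev = make_events([0.0, 0.5, 1.0, 1.5, 2.0])
        sig = gp.RawGaitSignal(np.zeros(500), 100.0, 20.0)
        with pytest.raises(InsufficientDataError):
            gp.spatiotemporal(ev, sig)


class TestGaitAsymmetry:
    def test_equal_swing_times_give_zero(self):
        assert gp.gait_asymmetry(0.42, 0.42) == 0.0

    def test_side_swap_invariance(self):
        assert gp.gait_asymmetry(0.40, 0.44) == pytest.approx(
            gp.gait_asymmetry(0.44, 0.40)
        )

    def test_reference_value(self):
        # 100 * |ln(0.44 / 0.40)|
        assert gp.gait_asymmetry(0.40, 0.44) == pytest.approx(
            100 * abs(np.log(0.44 / 0.40))
        )
        assert gp.gait_asymmetry(0.40, 0.44) == pytest.approx(9.531, abs=5e-4)

    def test_nonpositive_swing_rejected(self):
        with pytest.raises(ValueError):
            gp.gait_asymmetry(0.0, 0.4)


class TestRegularity:
    def test_periodic_symmetric_signal_near_one(self, symmetric_trial):
        sig, ev = symmetric_trial
        reg = gp.regularity_autocorrelation(sig, ev)
        assert reg["step_regularity"] == pytest.approx(1.0, abs=0.05)
        assert reg["stride_regularity"] == pytest.approx(1.0, abs=0.05)
        assert reg["step_symmetry"] == pytest.approx(1.0, abs=0.02)

    def test_white_noise_regularity_near_zero(self):
        rng = np.random.default_rng(0)
        sig = gp.RawGaitSignal(rng.normal(size=6000), 100.0, 20.0)
        ev = make_events(np.arange(0.25, 59.5, 0.5))
        reg = gp.regularity_autocorrelation(sig, ev)
        assert abs(reg["step_regularity"]) < 0.1
        assert abs(reg["stride_regularity"]) < 0.1

    def test_needs_six_strides(self, symmetric_trial):
        sig, _ = symmetric_trial
        short = make_events(np.arange(0.25, 3.0, 0.5))
        with pytest.raises(InsufficientDataError):
            gp.regularity_autocorrelation(sig, short)


class TestVariabilityCV:
    def test_constant_intervals_give_zero(self):
        ev = make_events(np.arange(0.0, 10.0, 0.5), toe_offs=True)
        out = gp.variability_cv(ev)
        assert out["stride_time_cv"] == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_value(self):
        # one side's stride intervals {1.0, 1.0, 1.2, 0.8, 1.0}:
        # mean 1.0, sample sd sqrt(0.08/4) = 0.141421 -> CV 14.142%
        left = np.concatenate([[0.0], np.cumsum([1.0, 1.0, 1.2, 0.8, 1.0])])
        right = left[:-1] + 0.5
        ev = gp.GaitEventSeries(left, right)
        out = gp.variability_cv(ev)
        assert out["stride_time_cv"] == pytest.approx(
            100 * np.std([1.0, 1.0, 1.2, 0.8, 1.0], ddof=1) / 1.0
        )
        assert out["stride_time_cv"] == pytest.approx(14.142, abs=5e-4)

    def test_scale_invariance(self):
        times = np.concatenate([[0.0], np.cumsum([1.0, 1.1, 0.9, 1.0, 1.05, 0.95])])
        ev1 = gp.GaitEventSeries(times, times[:-1] + 0.5)
        ev2 = gp.GaitEventSeries(2 * times, 2 * (times[:-1] + 0.5))
        assert gp.variability_cv(ev1)["stride_time_cv"] == pytest.approx(
            gp.variability_cv(ev2)["stride_time_cv"]
        )

    def test_generator_cv_monotonically_increases_measured_cv(self):
        """Measured stride-time CV tracks the generator's step-interval CV."""
        from scipy.stats import spearmanr
        levels = np.linspace(0.0, 0.10, 11)
        gen_cv, meas = [], []
        for cv in levels:
            for seed in range(3):
                spec = gp.SignalSpec(duration=60, step_time_cv=float(cv),
                                     noise_sd=0.0, seed=seed)
                _, ev = gp.generate_signal(spec)
                out = gp.variability_cv(ev)
                gen_cv.append(cv)
                meas.append(out["stride_time_cv"])
        rho = spearmanr(gen_cv, meas).statistic
        assert rho > 0.9


class TestPhaseCoordination:
    def test_perfect_antiphase_gives_zero(self):
        left = np.arange(0.0, 8.0, 1.0)
        right = left[:-1] + 0.5
        out = gp.phase_coordination(gp.GaitEventSeries(left, right))
        assert out["pci"] == pytest.approx(0.0, abs=1e-9)
        assert out["phase_cv"] == pytest.approx(0.0, abs=1e-9)
        assert out["phase_abs_diff"] == pytest.approx(0.0, abs=1e-9)

    def test_hand_constructed_phase_sequence(self):
        """pci = 100*sd/mean + 100*mean|phi-180|/180 on the phi sequence."""
        phis = np.array([170.0, 180.0, 190.0, 180.0, 180.0])
        left = np.arange(0.0, 6.0, 1.0)
        right = left[:-1] + phis / 360.0
        out = gp.phase_coordination(gp.GaitEventSeries(left, right))
        exp_cv = 100 * np.std(phis, ddof=1) / np.mean(phis)
        exp_abs = 100 * np.mean(np.abs(phis - 180)) / 180
        assert out["phase_cv"] == pytest.approx(exp_cv)
        assert out["phase_abs_diff"] == pytest.approx(exp_abs)
        assert out["pci"] == pytest.approx(exp_cv + exp_abs)

    def test_constant_phase_shift_keeps_cv_zero(self):
        left = np.arange(0.0, 8.0, 1.0)
        out = gp.phase_coordination(gp.GaitEventSeries(left, left[:-1] + 0.45))
        assert out["phase_cv"] == pytest.approx(0.0, abs=1e-9)
        assert out["phase_abs_diff"] > 0

    def test_mostly_missing_contralateral_flags_undefined(self):
        left = np.arange(0.0, 8.0, 1.0)
        right = np.array([0.5, 1.5])  # 5 of 7 strides lack a contralateral strike
        out = gp.phase_coordination(gp.GaitEventSeries(left, right))
        assert np.isnan(out["pci"])


class TestPSDFeatures:
    def test_single_tone_recovered_within_a_bin(self):
        t = np.arange(0, 30, 0.01)
        sig = gp.RawGaitSignal(np.sin(2 * np.pi * 2.0 * t), 100.0, 20.0)
        out = gp.psd_features(sig)
        assert out["dominant_frequency"] == pytest.approx(2.0, abs=0.2)

    def test_stronger_tone_wins(self):
        t = np.arange(0, 30, 0.01)
        x = 1.0 * np.sin(2 * np.pi * 1.5 * t) + 2.0 * np.sin(2 * np.pi * 2.5 * t)
        out = gp.psd_features(gp.RawGaitSignal(x, 100.0, 20.0))
        assert abs(out["dominant_frequency"] - 2.5) <= 0.2
        assert abs(out["dominant_frequency"] - 1.5) > 0.5

    def test_amplitude_scaling_quadruples_peak_power_only(self):
        t = np.arange(0, 30, 0.01)
        x = np.sin(2 * np.pi * 2.0 * t)
        out1 = gp.psd_features(gp.RawGaitSignal(x, 100.0, 20.0))
        out2 = gp.psd_features(gp.RawGaitSignal(2 * x, 100.0, 20.0))
        assert out2["amplitude_dominant_frequency"] == pytest.approx(
            4 * out1["amplitude_dominant_frequency"], rel=1e-9
        )
        assert out2["dominant_frequency"] == out1["dominant_frequency"]
        assert out2["width_dominant_frequency"] == pytest.approx(
            out1["width_dominant_frequency"], rel=1e-9
        )

    def test_short_signal_rejected(self):
        sig = gp.RawGaitSignal(np.random.default_rng(1).normal(size=500), 100.0, 20.0)
        with pytest.raises(InsufficientDataError):
            gp.psd_features(sig)


class TestExtractAndFilter:
    def test_two_identical_trials_equal_single(self, symmetric_trial):
        sig, ev = symmetric_trial
        one = gp.extract_trial(sig, ev)
        two = gp.extract_all([sig, sig], [ev, ev])
        np.testing.assert_allclose(
            one.to_numpy(), two.to_numpy(), rtol=1e-12, equal_nan=True
        )

    def test_trial_averaging_is_elementwise_mean(self):
        s1, e1 = gp.generate_signal(gp.SignalSpec(duration=16, seed=1))
        s2, e2 = gp.generate_signal(gp.SignalSpec(duration=24, seed=2))
        v1, v2 = gp.extract_trial(s1, e1), gp.extract_trial(s2, e2)
        avg = gp.extract_all([s1, s2], [e1, e2])
        assert avg["gait_speed"] == pytest.approx(
            (v1["gait_speed"] + v2["gait_speed"]) / 2
        )

    def test_undefined_value_propagates_from_other_trial(self):
        # 12 s trial: long enough for PCI; 11 s with one-sided events is not
        s1, e1 = gp.generate_signal(gp.SignalSpec(duration=20, seed=1))
        s2, e2 = gp.generate_signal(gp.SignalSpec(duration=20, seed=2))
        # remove most right strikes so PCI is undefined in trial 2
        e2 = gp.GaitEventSeries(e2.left_heel_strikes, e2.right_heel_strikes[:2],
                                e2.left_toe_offs, np.array([]))
        v1 = gp.extract_trial(s1, e1)
        avg = gp.extract_all([s1, s2], [e1, e2])
        assert avg["pci"] == pytest.approx(v1["pci"])

    def test_zero_trials_rejected(self):
        with pytest.raises(InsufficientDataError):
            gp.extract_all([])

    def test_offset_invariance_after_detrending(self, symmetric_trial):
        sig, ev = symmetric_trial
        shifted = gp.RawGaitSignal(sig.samples + 5.0, sig.sampling_rate,
                                   sig.walk_distance)
        v1 = gp.extract_trial(sig, ev)
        v2 = gp.extract_trial(shifted, ev)
        np.testing.assert_allclose(
            v1.to_numpy(), v2.to_numpy(), rtol=1e-6, atol=1e-9, equal_nan=True
        )

    def test_stance_plus_swing_is_100_per_side(self, asymmetric_trial):
        sig, ev = asymmetric_trial
        v = gp.extract_trial(sig, ev)
        for side in ("left", "right"):
            total = v[f"stance_percent_{side}"] + v[f"swing_percent_{side}"]
            assert total == pytest.approx(100.0, abs=0.01)

    def test_speed_filter_bounds_and_log(self):
        import pandas as pd
        table = pd.DataFrame({"id": list("abcd"),
                              "gait_speed": [0.2, 0.8, 1.3, 2.4]})
        kept, excluded = gp.speed_validity_filter(table)
        assert list(kept["id"]) == ["b", "c"]
        assert list(excluded["id"]) == ["a", "d"]

    def test_speed_filter_identity_when_all_in_range(self):
        import pandas as pd
        table = pd.DataFrame({"id": ["a", "b"], "gait_speed": [1.0, 1.5]})
        kept, excluded = gp.speed_validity_filter(table)
        assert len(kept) == 2 and len(excluded) == 0

    def test_speed_filter_fast_walker_restriction(self):
        import pandas as pd
        table = pd.DataFrame({"id": list("abc"), "gait_speed": [1.0, 1.7, 1.9]})
        kept, _ = gp.speed_validity_filter(table, high=1.8)
        assert list(kept["id"]) == ["a", "b"]

    def test_speed_filter_misconfiguration(self):
        import pandas as pd
        with pytest.raises(ConfigError):
            gp.speed_validity_filter(
                pd.DataFrame({"gait_speed": [1.0]}), low=2.0, high=1.0
            )
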