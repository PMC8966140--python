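"""Sensor ingestion, EOG drift correction, fusion, saccade detection."""

import numpy as np
import pandas as pd
import pytest

from selfmotion.trajectories import (MotionRecording, correct_eog_drift,
                                     detect_saccades, fuse,
                                     recording_from_files)

F_EOG = 33.0
F_HEAD = 200.0


def make_recording(duration=30.0, head_yaw=None, eye=None, torso=None):
    n_h = int(duration * F_HEAD) + 1
    n_e = int(duration * F_EOG) + 1
    t_h = np.arange(n_h) / F_HEAD
    t_e = np.arange(n_e) / F_EOG
    return MotionRecording(
        t_head=t_h,
        head_yaw=np.full(n_h, 0.0) if head_yaw is None else head_yaw(t_h),
        head_translation_xy=np.zeros((n_h, 2)),
        torso_yaw=np.zeros(n_h) if torso is None else torso(t_h),
        t_eog=t_e,
        eog_raw=np.zeros(n_e) if eye is None else eye(t_e),
    )


class TestDriftCorrection:
    def test_constant_input_maps_to_zero(self):
        out = correct_eog_drift(np.full(2000, 7.0))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_sinusoid_survives_linear_drift_removal(self):
        t = np.arange(0, 60, 1 / F_EOG)
        sig = 5.0 * np.sin(2 * np.pi * 2.0 * t)
        drift = np.linspace(0.0, 20.0, t.size)
        out = correct_eog_drift(sig + drift)
        assert np.corrcoef(out, sig)[0, 1] > 0.99
        assert abs(np.mean(out)) < 0.5

    def test_pure_ramp_leaves_small_interior_residual(self):
        ramp = np.linspace(0.0, 20.0, 2000)
        out = correct_eog_drift(ramp)
        interior = out[300:-300]
        assert np.abs(interior).max() < 0.01 * 20.0

    def test_series_shorter_than_window_raises(self):
        with pytest.raises(ValueError):
            correct_eog_drift(np.zeros(400), window=500)

    def test_random_walk_drift_removed_steps_preserved(self):
        """The corrector removes >= 95% of random-walk drift variance
        (median over seeds, 600 s records) while saccadic step amplitudes
        survive within 10%.  The drift residual is isolated through the
        corrector's linearity: correct(clean + rw) - correct(clean)."""
        removals, step_errs = [], []
        duration = 600.0
        n = int(duration * F_EOG)
        t = np.arange(n) / F_EOG
        steps = [(20.0 + 20.0 * k, 15.0 * (-1) ** k) for k in range(11)]
        clean = np.zeros(n)
        for tc, a in steps:
            clean[t >= tc] += a
        for seed in range(10):
            rw = np.cumsum(
                np.random.default_rng(seed).normal(0.0, 0.05, n))
            out = correct_eog_drift(clean + rw)
            resid = out - correct_eog_drift(clean)
            removals.append(1.0 - np.var(resid) / np.var(rw))
            errs = []
            for tc, a in steps:
                i = int(tc * F_EOG)
                before = np.median(out[i - 10:i - 1])
                after = np.median(out[i + 2:i + 11])
                errs.append(abs((after - before) - a) / abs(a))
            step_errs.append(np.median(errs))
        assert np.median(removals) >= 0.95
        assert np.median(step_errs) <= 0.10


class TestFuse:
    def test_constant_streams_fuse_exactly(self):
        rec = make_recording(head_yaw=lambda t: np.full(t.size, 10.0),
                             eye=lambda t: np.full(t.size, 5.0))
        g = fuse(rec, correct_drift=False)
        assert np.all(g.head_yaw == 10.0)
        assert np.all(g.gaze == 15.0)
        assert abs(g.fs - 120.0) < 1e-9

    def test_gaze_is_head_plus_eye_identity(self):
        rec = make_recording(
            head_yaw=lambda t: 10.0 * np.sin(0.5 * t),
            eye=lambda t: 4.0 * np.cos(0.3 * t))
        g = fuse(rec, correct_drift=False)
        assert np.array_equal(g.gaze, g.head_yaw + g.eye_in_head)

    def test_empty_eye_stream_rejected(self):
        with pytest.raises(ValueError):
            MotionRecording(
                t_head=np.arange(100) / F_HEAD,
                head_yaw=np.zeros(100),
                head_translation_xy=np.zeros((100, 2)),
                torso_yaw=np.zeros(100),
                t_eog=np.array([]), eog_raw=np.array([]))

    def test_non_overlapping_streams_rejected(self):
        rec = make_recording(duration=30.0)
        rec.t_eog = rec.t_eog + 100.0
        with pytest.raises(ValueError):
            fuse(rec)

    def test_head_step_lands_within_one_fused_sample(self):
        rec = make_recording(
            duration=20.0,
            head_yaw=lambda t: np.where(t >= 10.0, 30.0, 0.0))
        g = fuse(rec, correct_drift=False, detect=False)
        after = g.gaze[g.t > 10.0 + 1.0 / 120.0]
        before = g.gaze[g.t < 10.0 - 1.0 / 120.0]
        assert np.allclose(after, 30.0, atol=0.5)
        assert np.allclose(before, 0.0, atol=0.5)

    def test_relative_to_torso_series(self):
        rec = make_recording(
            head_yaw=lambda t: np.full(t.size, 25.0),
            eye=lambda t: np.full(t.size, 5.0),
            torso=lambda t: np.full(t.size, 10.0))
        g = fuse(rec, correct_drift=False)
        assert np.allclose(g.head_re_torso, 15.0)
        assert np.allclose(g.gaze_re_torso, 20.0)


class TestSaccadeDetection:
    FS = 120.0

    @staticmethod
    def steps_series(t, step_times, amp=20.0, rise=0.1):
        x = np.zeros(t.size)
        for k, tc in enumerate(step_times):
            a = amp * (-1) ** k
            ramp = (t >= tc) & (t < tc + rise)
            x[t >= tc + rise] += a
            x[ramp] += a * 0.5 * (1 - np.cos(np.pi * (t[ramp] - tc) / rise))
        return x

    def test_constant_series_has_no_saccades(self):
        assert detect_saccades(np.zeros(600), self.FS, 50.0) == []

    def test_three_steps_give_three_events(self):
        t = np.arange(0, 60, 1 / self.FS)
        x = self.steps_series(t, [10.0, 25.0, 40.0])
        events = detect_saccades(x, self.FS, 50.0)
        assert len(events) == 3
        assert all(abs(e.amplitude - 20.0) < 2.0 for e in events)
        assert all(e.offset > e.onset for e in events)

    def test_slow_ramp_below_threshold_ignored(self):
        # 2 deg/s, well below the 50 deg/s eye threshold
        x = np.linspace(0.0, 20.0, int(10 * self.FS))
        assert detect_saccades(x, self.FS, 50.0) == []

    def test_small_amplitude_events_dropped(self):
        t = np.arange(0, 20, 1 / self.FS)
        x = self.steps_series(t, [10.0], amp=2.0, rise=0.02)
        assert detect_saccades(x, self.FS, 50.0, min_amp=3.0) == []

    def test_ground_truth_count_recovered_from_generator(self):
        """Well-separated generated saccades are counted exactly."""
        from selfmotion.measures import TargetTrack
        from selfmotion.synthdata import BehaviorProfile, generate_behavior
        from selfmotion.trajectories import fuse as do_fuse
        times = np.arange(0.0, 60.0, 6.0)
        azs = np.where(np.arange(times.size) % 2 == 0, 25.0, -25.0)
        target = TargetTrack(times, azs.astype(float))
        profile = BehaviorProfile(head_contribution=0.7,
                                  saccade_rate_scale=0.0,
                                  eog_noise_sigma=0.0,
                                  eog_drift_step_sigma=0.0,
                                  head_tremor_sigma=0.0)
        for seed in (0, 1, 2):
            ds = generate_behavior(target, profile, 60.0, seed=seed)
            g = do_fuse(ds.recording, correct_drift=False)
            assert len(g.saccades["gaze"]) == len(ds.true_events)


class TestFileIO:
    def test_round_trip_through_delimited_text(self, tmp_path):
        rec = make_recording(duration=5.0,
                             head_yaw=lambda t: 3.0 * np.sin(t))
        head = tmp_path / "head.csv"
        eye = tmp_path / "eye.csv"
        pd.DataFrame({
            "t": rec.t_head, "head_yaw": rec.head_yaw,
            "head_x": rec.head_translation_xy[:, 0],
            "head_y": rec.head_translation_xy[:, 1],
            "torso_yaw": rec.torso_yaw,
        }).to_csv(head, index=False)
        pd.DataFrame({"t": rec.t_eog, "eog": rec.eog_raw}
                     ).to_csv(eye, index=False)
        back = recording_from_files(head, eye)
        assert np.allclose(back.head_yaw, rec.head_yaw)
        assert np.allclose(back.t_eog, rec.t_eog)

    def test_non_monotone_time_rejected(self, tmp_path):
        p = tmp_path / "eye.csv"
        pd.DataFrame({"t": [0.0, 0.2, 0.1], "eog": [0, 0, 0]}
                     ).to_csv(p, index=False)
        from selfmotion.trajectories import read_eye_stream
        with pytest.raises(ValueError):
            read_eye_stream(p)
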