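"""Better-ear segmental SNR, reference, SNRrelative, ADM improvement."""

import numpy as np
import pytest

from selfmotion.adm import AdmConfig, form_cardioids, _combine_with_betas
from selfmotion.scene import HeadPose, ParametricHarir, SceneSpec, Source
from selfmotion.snr import (SnrTrack, reference_snr, render_scene_to_mics,
                            segmental_snr, snr_improvement_adm, snr_relative)

FS = 16000


def naive_segmental_snr(tl, nl, tr, nr, fs, window_len=0.2,
                        clamp=(-10.0, 35.0)):
    """Independent per-window loop oracle with identical clamping."""
    win = int(round(window_len * fs))
    n_win = len(tl) // win
    left, right = [], []
    for ear, (t, nn) in (("L", (tl, nl)), ("R", (tr, nr))):
        vals = []
        for w in range(n_win):
            ts = t[w * win:(w + 1) * win]
            ns = nn[w * win:(w + 1) * win]
            pt, pn = np.sum(ts ** 2), np.sum(ns ** 2)
            if pn == 0.0:
                v = clamp[1]
            elif pt == 0.0:
                v = clamp[0]
            else:
                v = min(max(10 * np.log10(pt / pn), clamp[0]), clamp[1])
            vals.append(v)
        (left if ear == "L" else right).append(vals)
    return np.array(left[0]), np.array(right[0])


def make_scene(fs=FS, duration=2.0, target_az=20.0, noise_az=-100.0,
               seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    return SceneSpec(
        sources=[
            Source(signal=rng.standard_normal(n), azimuth=target_az,
                   role="target"),
            Source(signal=rng.standard_normal(n), azimuth=noise_az,
                   role="noise"),
        ],
        duration=duration, sample_rate=fs)


class TestSegmentalSnr:
    def test_identical_signals_give_zero_db_every_window(self, rng):
        x = rng.standard_normal(FS)
        track = segmental_snr((x, x), (x, x), sample_rate=FS)
        assert np.all(track.left == 0.0)
        assert np.all(track.better_ear == 0.0)

    def test_silent_noise_clamps_high(self, rng):
        x = rng.standard_normal(FS)
        z = np.zeros(FS)
        track = segmental_snr((x, x), (z, z), sample_rate=FS)
        assert np.all(track.left == 35.0)

    def test_amplitude_ratio_two_gives_six_db(self):
        t = np.arange(FS) / FS
        s = np.sin(2 * np.pi * 440 * t)
        track = segmental_snr((2 * s, 2 * s), (s, s), sample_rate=FS)
        assert np.allclose(track.left, 20 * np.log10(2.0), atol=1e-6)

    def test_window_count_is_floor_of_duration_ratio(self, rng):
        x = rng.standard_normal(int(1.35 * FS))
        track = segmental_snr((x, x), (x, x), sample_rate=FS)
        assert track.n_windows == int(np.floor(1.35 / 0.2))

    def test_matches_naive_per_window_loop_exactly(self, rng):
        n = int(2.3 * FS)
        tl, tr = rng.standard_normal(n), 0.3 * rng.standard_normal(n)
        nl, nr = rng.standard_normal(n), rng.standard_normal(n)
        # plant degenerate windows: silent noise, silent target
        nl[:3200] = 0.0
        tl[3200:6400] = 0.0
        track = segmental_snr((tl, tr), (nl, nr), sample_rate=FS)
        oL, oR = naive_segmental_snr(tl, nl, tr, nr, FS)
        assert np.array_equal(track.left, oL)
        assert np.array_equal(track.right, oR)

    def test_better_ear_monotone_in_single_ear_improvement(self, rng):
        n = 2 * FS
        tl, tr = rng.standard_normal(n), rng.standard_normal(n)
        nl, nr = rng.standard_normal(n), rng.standard_normal(n)
        base = segmental_snr((tl, tr), (nl, nr), sample_rate=FS)
        # improving the left ear's SNR in every window (quieter noise)
        better = segmental_snr((tl, tr), (0.5 * nl, nr), sample_rate=FS)
        assert np.all(better.better_ear >= base.better_ear)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            segmental_snr((np.zeros(10), np.zeros(10)),
                          (np.zeros(10), np.zeros(10)), sample_rate=FS)


class TestReferenceAndRelative:
    def test_track_against_itself_is_exactly_zero(self, rng):
        x = rng.standard_normal(2 * FS)
        track = segmental_snr((x, x), (0.3 * x, x), sample_rate=FS)
        assert snr_relative(track, track) == 0.0

    def test_explicit_zero_pose_equals_no_pose(self, harir16k):
        spec = make_scene()
        ref_mean, ref_track = reference_snr(spec, harir16k)
        still = HeadPose.still(spec.duration)
        tgt, noi = render_scene_to_mics(spec, harir16k, pose=still)
        track = segmental_snr(tgt, noi)
        assert np.allclose(track.better_ear, ref_track.better_ear,
                           atol=1e-9)
        assert snr_relative(track, ref_track) == pytest.approx(0.0, abs=1e-9)

    def test_scene_rotation_with_pose_leaves_summaries_unchanged(
            self, harir16k):
        """Rotating all sources and the head by the same ring-slot angle
        is a relabelling of directions: SNR summaries move < 0.1 dB."""
        spec = make_scene(target_az=11.25, noise_az=-78.75)
        ref, _ = reference_snr(spec, harir16k)
        rot = 45.0
        spec_rot = make_scene(target_az=11.25 + rot, noise_az=-78.75 + rot)
        pose = HeadPose(np.array([0.0, spec.duration]),
                        np.array([rot, rot]), np.zeros((2, 2)))
        tgt, noi = render_scene_to_mics(spec_rot, harir16k, pose=pose)
        track = segmental_snr(tgt, noi)
        assert track.mean == pytest.approx(ref, abs=0.1)


class TestAdmImprovement:
    def test_pass_through_adm_gives_zero_improvement(self, harir16k):
        """With beta frozen at 0 the processed path is the compensated
        front cardioid; comparing it against the identically processed
        'unprocessed' signals gives exactly zero improvement."""
        spec = make_scene(duration=1.2)
        tgt, noi = render_scene_to_mics(spec, harir16k)
        cfg = AdmConfig(fs=FS, mu=0.0)
        sides = {}
        for side in ("left", "right"):
            tf, tr = tgt.pair(side)
            nf, nr = noi.pair(side)
            n_blocks = int(np.ceil(len(tf) / cfg.block))
            betas = np.zeros(n_blocks)
            ct_f, ct_b = form_cardioids(tf, tr, cfg)
            cn_f, cn_b = form_cardioids(nf, nr, cfg)
            sides[side] = (
                _combine_with_betas(ct_f, ct_b, betas, cfg),
                _combine_with_betas(cn_f, cn_b, betas, cfg))
        proc = segmental_snr((sides["left"][0], sides["right"][0]),
                             (sides["left"][1], sides["right"][1]),
                             sample_rate=FS)
        unproc = segmental_snr((sides["left"][0], sides["right"][0]),
                               (sides["left"][1], sides["right"][1]),
                               sample_rate=FS)
        assert snr_relative(proc, unproc) == 0.0

    def test_improvement_matches_fixed_beta_oracle(self, harir16k):
        """Replaying the recorded state trajectory block-by-block with a
        brute-force fixed-beta evaluation reproduces the improvement to
        0.1 dB (here: identical code path is avoided by recomputing the
        windowed SNRs from independently shadowed components)."""
        from selfmotion.adm import process_binaural
        spec = make_scene(duration=1.6, noise_az=150.0, seed=3)
        tgt, noi = render_scene_to_mics(spec, harir16k)
        cfg = AdmConfig(fs=FS)
        res = snr_improvement_adm(tgt, noi, cfg)

        # oracle: replay each side's recorded betas with an explicit
        # block loop + direct IIR filtering (no shared combiner code)
        from scipy.signal import lfilter
        from selfmotion.adm import adapt_and_combine

        def fixed_beta_output(front, rear, betas):
            c_f, c_b = form_cardioids(front, rear, cfg)
            y = np.empty_like(c_f)
            for k, b in enumerate(betas):
                i0, i1 = k * cfg.block, min((k + 1) * cfg.block, c_f.size)
                y[i0:i1] = c_f[i0:i1] - b * c_b[i0:i1]
                if i1 >= c_f.size:
                    break
            b_iir, a_iir = cfg.compensation_filter()
            return lfilter(b_iir, a_iir, y)

        outs = {}
        for side in ("left", "right"):
            tf, tr = tgt.pair(side)
            nf, nr = noi.pair(side)
            c_f, c_b = form_cardioids(tf + nf, tr + nr, cfg)
            _, state = adapt_and_combine(c_f, c_b, cfg)
            outs[side] = (fixed_beta_output(tf, tr, state.beta),
                          fixed_beta_output(nf, nr, state.beta))
        proc = segmental_snr((outs["left"][0], outs["right"][0]),
                             (outs["left"][1], outs["right"][1]),
                             sample_rate=FS)
        unproc = segmental_snr(tgt, noi)
        n = min(proc.n_windows, unproc.n_windows)
        oracle = float(np.mean(proc.better_ear[:n]
                               - unproc.better_ear[:n]))
        assert res["improvement"] == pytest.approx(oracle, abs=0.1)
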