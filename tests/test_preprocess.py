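import numpy as np
import pytest

from caplast.core import DffSession, TrialTrace, percentile
from caplast.errors import ValidationError
from caplast.preprocess import (
    dff_cerebellar,
    dff_s1,
    interpolate_artifact_frames,
    motion_correct_rigid,
    noise_sigma,
    smooth_savgol,
    snr,
    subtract_background,
)
from conftest import percentile_oracle


def make_trace(values, fr=30.98, onset=10, area="s1"):
    return TrialTrace(np.asarray(values, float), frame_rate=fr,
                      stim_onset_frame=onset, brain_area=area)


class TestArtifactInterpolation:
    def test_midpoint_of_neighbors(self):
        v = np.zeros((5, 1))
        v[:, 0] = [0, 2, 99, 4, 0]
        out = interpolate_artifact_frames(make_trace(v, onset=0), [2])
        assert out.values[2, 0] == 3.0
        assert np.array_equal(np.delete(out.values, 2), np.delete(v, 2))

    def test_no_artifacts_identity(self):
        v = np.random.default_rng(0).normal(size=(20, 3))
        out = interpolate_artifact_frames(make_trace(v, onset=0), [])
        assert np.array_equal(out.values, v)

    def test_edge_frame_rejected(self):
        with pytest.raises(ValidationError):
            interpolate_artifact_frames(make_trace(np.zeros((5, 1)), onset=0), [0])

    def test_restoration_error_bounded_by_curvature_on_smooth_trace(self):
        t = np.linspace(0, 4 * np.pi, 200)
        clean = np.sin(t)[:, None]
        corrupted = clean.copy()
        bad = [20, 50, 90, 150]
        corrupted[bad, 0] = 99.0
        out = interpolate_artifact_frames(make_trace(corrupted, onset=0), bad)
        # linear interpolation error of a C2 function <= max|f''| h^2 / 2
        h = t[1] - t[0]
        assert np.max(np.abs(out.values[bad, 0] - clean[bad, 0])) <= h**2 / 2 + 1e-12


class TestBackgroundSubtraction:
    def test_constant_background_subtracts_value(self):
        v = np.full((10, 2), 50.0)
        out = subtract_background(make_trace(v, onset=0), np.full(100, 7.0))
        assert np.allclose(out.values, 43.0)

    def test_p1_matches_sort_oracle_with_outlier(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(100, 5, 500)
        bg[123] = -40.0  # single low outlier pulls P1 down
        out = subtract_background(make_trace(np.zeros((5, 1)), onset=0), bg)
        assert np.allclose(out.values, -percentile_oracle(bg, 1.0))

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            subtract_background(make_trace(np.zeros((5, 1)), onset=0), [])


class TestSavgolSmoothing:
    def test_constant_unchanged(self):
        assert np.allclose(smooth_savgol(np.full(200, 3.3)), 3.3)

    def test_linear_ramp_fixed_point_everywhere(self):
        x = np.linspace(0, 10, 300)
        assert np.allclose(smooth_savgol(x), x, atol=1e-12)

    def test_interior_variance_reduced_by_window_factor(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 20000)
        sm = smooth_savgol(x)[25:-25]
        assert sm.var() == pytest.approx(1 / 51, rel=0.15)

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            smooth_savgol(np.zeros(50))


class TestDffS1:
    def test_constant_positive_trace_gives_zero_dff(self):
        sess = dff_s1(make_trace(np.full((100, 2), 5.0), onset=0))
        assert sess.f0 == pytest.approx(5.0)
        assert np.allclose(sess.dff, 0.0)

    def test_negative_f0_flags_rejection(self):
        v = np.full((200, 1), -1.0)
        v[:100] = 10.0  # P1 of smoothed trace goes negative
        sess = dff_s1(make_trace(v, onset=0))
        assert sess.rejected and sess.dff is None

    def test_zero_f0_is_an_error_not_a_rejection(self):
        with pytest.raises(ValidationError):
            dff_s1(make_trace(np.zeros((100, 1)), onset=0))

    def test_rejection_rate_zero_on_noiseless_positive_sessions(self, small_session):
        cfg, traces, _ = small_session
        assert not any(dff_s1(tr).rejected for tr in traces)

    def test_noiseless_peak_amplitude_tracks_ground_truth(self):
        from caplast.synth import SynthSessionConfig, generate_calcium_session

        cfg = SynthSessionConfig(
            n_rois=1, n_trials_pre=1, n_trials_post=1, frames_per_trial=620,
            spont_rate=0.0, evoked_prob=1.0, latency_jitter_ms=0.0,
            amp_sd=0.0, noise_sd=0.0, seed=0,
        )
        traces, truth = generate_calcium_session(cfg)
        sess = dff_s1(traces[0])
        # 51-frame smoothing spreads the transient: the peak falls below the
        # impulse amplitude but the transient integral is conserved, so
        # compare window integrals instead of peaks.
        f_ev = truth.evoked_frames[0, 0]
        dff = sess.dff[:, 0]
        got = dff[max(f_ev - 30, 0):f_ev + 90].sum()
        want = cfg.amp_mean / (1 - cfg.gamma)
        assert got == pytest.approx(want, rel=0.05)


class TestDffCerebellar:
    def test_constant_trace_gives_zero(self):
        sess = dff_cerebellar(make_trace(np.full((60, 2), 4.0), onset=10, area="cerebellum"))
        assert np.allclose(sess.dff, 0.0)

    def test_pre_stimulus_mean_zero_for_any_input(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(50, 150, size=(80, 4))
        sess = dff_cerebellar(make_trace(v, onset=20, area="cerebellum"))
        pre = sess.dff[15:20]
        assert np.allclose(pre.mean(axis=0), 0.0, atol=1e-12)

    def test_f0_is_p20_order_statistic(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(10, 20, size=(10, 1))
        sess = dff_cerebellar(make_trace(v, onset=6, area="cerebellum"))
        assert sess.f0[0] == pytest.approx(percentile_oracle(v[:, 0], 20.0))

    def test_too_few_pre_stimulus_frames_rejected(self):
        with pytest.raises(ValidationError):
            dff_cerebellar(make_trace(np.ones((60, 1)), onset=3))


class TestNoiseSigma:
    def make_session(self, dff, fr=30.98):
        return DffSession(dff=np.asarray(dff, float), f0=1.0, frame_rate=fr,
                          stim_onset_frame=0)

    def test_constant_dff_zero_sigma(self):
        assert noise_sigma(self.make_session(np.zeros((200, 1)))) == 0.0

    def test_quiet_segment_sets_sigma_on_piecewise_trace(self):
        rng = np.random.default_rng(5)
        quiet = rng.normal(0, 0.01, 400)
        active = rng.normal(0, 0.5, 400)
        x = np.concatenate([quiet, active])[:, None]
        sigma = noise_sigma(self.make_session(x))
        # P1 of window SDs ~ the quiet-segment SD, far below the active SD
        assert sigma == pytest.approx(0.01, rel=0.3)
        # explicit enumeration oracle over all stride-1 windows
        sds = np.array([x[i:i + 155, 0].std(ddof=1) for i in range(800 - 154)])
        assert sigma == pytest.approx(percentile_oracle(sds, 1.0), abs=1e-12)

    def test_sigma_never_exceeds_global_sd(self, small_session):
        cfg, traces, _ = small_session
        for tr in traces:
            sess = dff_s1(tr)
            assert noise_sigma(sess) <= sess.session_trace().std(ddof=1) + 1e-12

    def test_short_session_rejected(self):
        with pytest.raises(ValidationError):
            noise_sigma(self.make_session(np.zeros((100, 1))))


class TestSnr:
    def test_scales_linearly_with_signal(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (400, 1))
        s1 = snr(DffSession(dff=x, f0=1.0, frame_rate=31.0, stim_onset_frame=0), 0.5)
        s2 = snr(DffSession(dff=3 * x, f0=1.0, frame_rate=31.0, stim_onset_frame=0), 0.5)
        assert s2 == pytest.approx(3 * s1)

    def test_gaussian_noise_snr_near_p95_of_standard_normal(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.2, (50000, 1))
        val = snr(DffSession(dff=x, f0=1.0, frame_rate=31.0, stim_onset_frame=0), 0.2)
        assert val == pytest.approx(1.645, abs=0.03)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValidationError):
            snr(DffSession(dff=np.zeros((10, 1)), f0=1.0, frame_rate=31.0,
                           stim_onset_frame=0), 0.0)

    def test_snr_rises_with_event_amplitude(self):
        from caplast.synth import SynthSessionConfig, generate_calcium_session

        vals = []
        for amp in (0.2, 0.5, 1.0):
            cfg = SynthSessionConfig(
                n_rois=1, n_trials_pre=4, n_trials_post=4, frames_per_trial=310,
                amp_mean=amp, amp_sd=0.0, noise_sd=5.0, evoked_prob=1.0,
                spont_rate=0.2, seed=8,
            )
            traces, _ = generate_calcium_session(cfg)
            sess = dff_s1(traces[0])
            vals.append(snr(sess, noise_sigma(sess)))
        assert vals[0] < vals[1] < vals[2]


class TestMotionCorrection:
    def make_stack(self, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 1, (64, 64))
        return base

    def test_unshifted_stack_all_zero_shifts(self):
        base = self.make_stack()
        stack = np.stack([base] * 4)
        _, shifts = motion_correct_rigid(stack, reference=base)
        assert np.array_equal(shifts, np.zeros((4, 2), int))

    def test_known_shift_recovered_and_reversed(self):
        base = self.make_stack(1)
        shifted = np.roll(base, (2, 3), axis=(0, 1))
        corrected, shifts = motion_correct_rigid(
            np.stack([base, shifted]), reference=base
        )
        assert tuple(shifts[1]) == (2, 3)
        assert np.allclose(corrected[1], base)

    def test_intensity_scaling_invariance(self):
        base = self.make_stack(2)
        shifted = 5.0 * np.roll(base, (1, -2), axis=(0, 1)) + 2.0
        _, shifts = motion_correct_rigid(np.stack([shifted]), reference=base)
        assert tuple(shifts[0]) == (1, -2)

    def test_exhaustive_search_oracle_agreement(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 1, (32, 32))
        frame = np.roll(base, (-3, 4), axis=(0, 1)) + rng.normal(0, 0.05, (32, 32))
        _, shifts = motion_correct_rigid(np.stack([frame]), reference=base,
                                         search_radius=6)
        # brute-force normalized correlation over all shifts in the radius
        best, arg = -np.inf, None
        f0 = frame - frame.mean()
        r0 = base - base.mean()
        for dy in range(-6, 7):
            for dx in range(-6, 7):
                cand = np.roll(frame, (-dy, -dx), axis=(0, 1))
                c = np.sum((cand - cand.mean()) * r0)
                c /= np.linalg.norm(cand - cand.mean()) * np.linalg.norm(r0)
                if c > best + 1e-12:
                    best, arg = c, (dy, dx)
        assert tuple(shifts[0]) == arg

    def test_empty_stack_rejected(self):
        with pytest.raises(ValidationError):
            motion_correct_rigid(np.zeros((0, 8, 8)))
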