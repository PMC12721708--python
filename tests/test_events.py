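import numpy as np
import pytest
from scipy.signal import lfilter

from caplast.deconv import EventRaster
from caplast.errors import NoEvokedWindowError, ValidationError
from caplast.events import (
    PEventProfile,
    compute_pevent,
    detect_spontaneous,
    epsp_metrics,
    evoked_window,
    persistent_cells,
    select_evoked_trials,
)
from caplast.synth import generate_epsp_sweep

FR = 30.98


def raster_from_binary(binary, fr=FR, onset=0, s_min=0.1):
    binary = np.asarray(binary, bool)
    return EventRaster(
        amplitudes=binary.astype(float) * s_min,
        binary=binary,
        s_min=s_min,
        frame_rate=fr,
        stim_onset_frame=onset,
    )


class TestDetectSpontaneous:
    def transient(self, amp, rise_frame=50, n=310, gamma=0.9):
        s = np.zeros(n)
        s[rise_frame] = amp
        return lfilter([1.0], [1.0, -gamma], s)

    def test_flat_trace_no_events(self):
        assert detect_spontaneous(np.zeros(300), FR) == []

    def test_single_transient_detected_with_onset_before_peak(self):
        x = self.transient(0.5)
        events = detect_spontaneous(x, FR)
        assert len(events) == 1
        ev = events[0]
        assert ev.onset_frame <= ev.peak_frame
        assert abs(ev.peak_frame - 50) <= 2
        assert ev.window.size == 31  # 1 s at 30.98 Hz

    def test_sub_prominence_transient_ignored(self):
        x = self.transient(0.05)
        assert detect_spontaneous(x, FR) == []

    def test_translation_equivariance(self):
        x = self.transient(0.5, rise_frame=60)
        shifted = np.concatenate([np.zeros(15), x])[:310]
        a = detect_spontaneous(x, FR)
        b = detect_spontaneous(shifted, FR)
        assert len(a) == len(b) == 1
        assert b[0].peak_frame - a[0].peak_frame == 15
        assert b[0].onset_frame - a[0].onset_frame == 15

    def test_window_zero_padded_when_overrunning_trial(self):
        x = self.transient(0.5, rise_frame=290, n=310)
        events = detect_spontaneous(x, FR)
        assert len(events) == 1
        assert events[0].truncated
        assert events[0].window.size == 31


class TestComputePevent:
    def test_proportion_definition(self):
        binary = np.zeros((20, 3), bool)
        binary[10, 0] = binary[10, 2] = True
        profile = compute_pevent(raster_from_binary(binary))
        assert profile.p[10] == pytest.approx(2 / 3)
        assert profile.p.sum() == pytest.approx(2 / 3)

    def test_empty_raster_zero_profile(self):
        profile = compute_pevent(raster_from_binary(np.zeros((30, 4), bool)))
        assert np.all(profile.p == 0) and profile.threshold == 0

    def test_single_trial_rejected(self):
        with pytest.raises(ValidationError):
            compute_pevent(raster_from_binary(np.zeros((30, 1), bool)))

    def test_adding_event_never_decreases_p(self):
        rng = np.random.default_rng(0)
        binary = rng.random((50, 8)) < 0.1
        p0 = compute_pevent(raster_from_binary(binary)).p
        binary2 = binary.copy()
        binary2[17, 3] = True
        p1 = compute_pevent(raster_from_binary(binary2)).p
        assert np.all(p1 >= p0)

    def test_poisson_null_max_run_short(self):
        """Under a Poisson-only raster, supra-threshold runs are isolated:
        the expected maximum run length stays below 2 frames."""
        rng = np.random.default_rng(1)
        max_runs = []
        for _ in range(100):
            binary = rng.random((620, 100)) < 0.003
            profile = compute_pevent(raster_from_binary(binary))
            supra = profile.p > profile.threshold
            run, best = 0, 0
            for v in supra:
                run = run + 1 if v else 0
                best = max(best, run)
            max_runs.append(best)
        assert np.mean(max_runs) < 2.0


class TestEvokedWindow:
    def profile(self, p, fr=FR):
        p = np.asarray(p, float)
        return PEventProfile(
            p=p, mean=float(p.mean()), sd=float(p.std()),
            threshold=float(p.mean() + 3 * p.std()), frame_rate=fr,
            n_trials=10,
        )

    def supra_profile(self, frames, n=310, level=0.9):
        p = np.zeros(n)
        p[frames] = level
        return self.profile(p)

    def test_twelve_frames_is_387_ms(self):
        prof = self.supra_profile(range(100, 112))
        w = evoked_window(prof, 90)
        assert (w.start_frame, w.end_frame) == (100, 112)
        assert w.duration_ms == 387

    def test_single_frame_is_32_ms(self):
        w = evoked_window(self.supra_profile([100]), 90)
        assert w.duration_ms == 32

    def test_no_supra_run_raises(self):
        with pytest.raises(NoEvokedWindowError):
            evoked_window(self.profile(np.zeros(100)), 10)

    def test_pre_onset_run_clipped_at_onset(self):
        prof = self.supra_profile(range(95, 108))
        w = evoked_window(prof, 100)
        assert (w.start_frame, w.end_frame) == (100, 108)

    def test_purely_pre_stimulus_run_discarded(self):
        prof = self.supra_profile(range(40, 50))
        with pytest.raises(NoEvokedWindowError):
            evoked_window(prof, 100)

    def test_longest_run_wins_earliest_on_ties(self):
        p = np.zeros(300)
        p[100:104] = 0.9
        p[200:204] = 0.9
        w = evoked_window(self.profile(p), 50)
        assert w.start_frame == 100


class TestSelectEvokedTrials:
    def test_empty_raster_non_responsive(self):
        r = raster_from_binary(np.zeros((50, 4), bool))
        from caplast.events import EvokedWindow

        w = EvokedWindow(start_frame=10, end_frame=14, duration_ms=129)
        assert select_evoked_trials(r, w).size == 0

    def test_all_trials_selected_when_all_hit(self):
        binary = np.zeros((50, 4), bool)
        binary[12, :] = True
        r = raster_from_binary(binary)
        from caplast.events import EvokedWindow

        w = EvokedWindow(start_frame=10, end_frame=14, duration_ms=129)
        assert np.array_equal(select_evoked_trials(r, w), np.arange(4))

    def test_matches_exhaustive_per_trial_scan(self):
        rng = np.random.default_rng(2)
        binary = rng.random((80, 20)) < 0.05
        r = raster_from_binary(binary)
        from caplast.events import EvokedWindow

        w = EvokedWindow(start_frame=30, end_frame=45, duration_ms=484)
        got = set(select_evoked_trials(r, w).tolist())
        want = {t for t in range(20) if binary[30:45, t].any()}
        assert got == want


class TestPersistentCells:
    @pytest.mark.parametrize(
        "a, b, expected",
        [({1, 2}, {3, 4}, set()), ({1, 2, 3}, {1, 2, 3}, {1, 2, 3}),
         ({1, 2, 5}, {2, 5, 9}, {2, 5})],
    )
    def test_intersection(self, a, b, expected):
        got = persistent_cells(a, b)
        assert got == expected
        assert got == {c for c in a if c in b}  # membership-scan oracle


class TestEpspMetrics:
    def test_amplitude_of_noiseless_peak(self):
        t, v, truth = generate_epsp_sweep(amplitude_mV=5.0, onset_ms=50.0,
                                          noise_sd=0.0)
        m = epsp_metrics(t, v, pulse_onset_ms=50.0)
        assert m.amplitude_mV == pytest.approx(5.0, abs=1e-3)
        assert m.latency_ms is not None and m.latency_ms >= 0

    def test_latency_matches_dense_grid_crossing(self):
        t, v, truth = generate_epsp_sweep(
            amplitude_mV=4.0, onset_ms=60.0, rise_tau_ms=3.0,
            decay_tau_ms=25.0, noise_sd=0.0, rate_hz=10000.0,
        )
        m = epsp_metrics(t, v, pulse_onset_ms=60.0)
        # dense-grid oracle: first time the analytic kernel crosses 10% of max
        tt = np.linspace(60.0, 200.0, 2_000_001)
        dt = tt - 60.0
        kern = np.exp(-dt / 25.0) - np.exp(-dt / 3.0)
        kern = kern / kern.max() * 4.0
        crossing = tt[kern > 0.4][0] - 60.0
        assert m.latency_ms == pytest.approx(crossing, abs=0.2)

    def test_flat_sweep_flagged(self):
        t = np.arange(0, 200, 0.1)
        v = np.full_like(t, -65.0)
        m = epsp_metrics(t, v, pulse_onset_ms=50.0)
        assert m.flagged and m.latency_ms is None

    def test_insufficient_baseline_rejected(self):
        t = np.arange(40, 200, 0.1)
        with pytest.raises(ValidationError):
            epsp_metrics(t, np.zeros_like(t), pulse_onset_ms=50.0)
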