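"""Event detection and evoked-window inference.

Spontaneous transients are found on the smoothed ΔF/F by a conjunction of
first- and second-difference thresholds (both ≥ 0.04 ΔF/F per frame at the
same frame) gating prominence-detected peaks (prominence ≥ 0.1 ΔF/F within
200 ms of a threshold crossing); the event onset is found by scanning
backward from the peak for the first frame whose first difference drops
below 0.05.

Evoked detection works on the binarized deconvolution raster: P^event is
the per-frame proportion of trials containing an event, and the evoked
window is the longest run of consecutive frames with P^event more than
three SDs above its mean, anchored at or after stimulus onset.  ``min_run``
sets the minimum admissible run length (default 1, so a single supra-
threshold frame is a 32 ms window at 30.98 Hz; raise it to ignore isolated
coincidence frames in spontaneously active sessions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import frames_to_ms, ms_to_frames, n_frames
from .deconv import EventRaster
from .errors import NoEvokedWindowError, ValidationError

__all__ = [
    "SpontaneousEvent",
    "PEventProfile",
    "EvokedWindow",
    "EpspMetrics",
    "detect_spontaneous",
    "compute_pevent",
    "evoked_window",
    "select_evoked_trials",
    "persistent_cells",
    "epsp_metrics",
]


@dataclass
class SpontaneousEvent:
    peak_frame: int
    onset_frame: int
    window: np.ndarray  # 1 s of ΔF/F from onset, zero-padded if truncated
    truncated: bool = False

    def __post_init__(self):
        if self.onset_frame > self.peak_frame:
            raise ValidationError("onset must not follow the peak")


@dataclass
class PEventProfile:
    """Per-frame proportion of trials with an event, with the mean + 3·SD
    threshold used for evoked-window selection."""

    p: np.ndarray
    mean: float
    sd: float
    threshold: float
    frame_rate: float
    n_trials: int


@dataclass
class EvokedWindow:
    """Half-open frame span [start_frame, end_frame) of supra-threshold
    P^event; duration is (end − start)/frame_rate, rounded to the ms."""

    start_frame: int
    end_frame: int
    duration_ms: int

    def __post_init__(self):
        if self.end_frame <= self.start_frame:
            raise ValidationError("evoked window must be non-empty")


@dataclass
class EpspMetrics:
    amplitude_mV: float
    latency_ms: float | None
    flagged: bool = False
    notes: str = ""


def detect_spontaneous(
    dff,
    frame_rate: float,
    d_thresh: float = 0.04,
    prominence: float = 0.1,
    match_ms: float = 200.0,
    onset_thresh: float = 0.05,
) -> list[SpontaneousEvent]:
    """Detect spontaneous calcium events on one smoothed ΔF/F trial.

    Thresholds are in ΔF/F per frame.  Events whose 1 s window overruns the
    trial end are kept with the window zero-padded and flagged.
    """
    x = np.asarray(dff, dtype=float).ravel()
    d1 = np.zeros_like(x)
    d1[1:] = np.diff(x)
    d2 = np.zeros_like(x)
    d2[2:] = np.diff(x, n=2)
    f_idx = np.nonzero((d1 >= d_thresh) & (d2 >= d_thresh))[0]
    peaks, _ = find_peaks(x, prominence=prominence)
    if f_idx.size == 0 or peaks.size == 0:
        return []
    match_frames = ms_to_frames(match_ms, frame_rate)
    win_len = n_frames(1.0, frame_rate)
    events = []
    for pk in peaks:
        if np.min(np.abs(f_idx - pk)) > match_frames:
            continue
        onset = pk
        while onset > 0 and d1[onset] >= onset_thresh:
            onset -= 1
        window = x[onset : onset + win_len]
        truncated = window.size < win_len
        if truncated:
            window = np.pad(window, (0, win_len - window.size))
        events.append(
            SpontaneousEvent(
                peak_frame=int(pk),
                onset_frame=int(onset),
                window=window.copy(),
                truncated=truncated,
            )
        )
    return events


def exclude_edge_frames(raster: EventRaster, n_edge: int) -> EventRaster:
    """Drop events in the first/last ``n_edge`` frames of every trial.

    Centered smoothing leaves the outermost frames of each trial under-
    smoothed (the symmetric window shrinks to nothing at the boundary), so
    their noise systematically exceeds an amplitude threshold calibrated on
    the smoothed interior.  Clearing the filter-transient frames removes
    that artifact; ``n_edge`` should be the smoothing half-window.
    """
    if n_edge < 0:
        raise ValidationError("n_edge must be >= 0")
    if n_edge == 0:
        return raster
    amps = raster.amplitudes.copy()
    binary = raster.binary.copy()
    amps[:n_edge] = 0.0
    amps[-n_edge:] = 0.0
    binary[:n_edge] = False
    binary[-n_edge:] = False
    return EventRaster(
        amplitudes=amps, binary=binary, s_min=raster.s_min,
        frame_rate=raster.frame_rate, stim_onset_frame=raster.stim_onset_frame,
    )


def compute_pevent(raster: EventRaster) -> PEventProfile:
    """P^event: per frame, the proportion of trials with at least one
    binary event; mean and SD taken over all frames of the trial-time axis."""
    if raster.n_trials < 2:
        raise ValidationError("P^event needs at least 2 trials")
    p = raster.binary.mean(axis=1)
    mean = float(p.mean())
    sd = float(p.std(ddof=0))
    return PEventProfile(
        p=p,
        mean=mean,
        sd=sd,
        threshold=mean + 3.0 * sd,
        frame_rate=raster.frame_rate,
        n_trials=raster.n_trials,
    )


def _runs_above(mask: np.ndarray):
    """Maximal runs of True as half-open (start, end) pairs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return list(zip(starts, ends))


def evoked_window(
    profile: PEventProfile, stim_onset_frame: int, min_run: int = 1
) -> EvokedWindow:
    """Longest run of consecutive supra-threshold P^event frames at or after
    stimulus onset (earliest run on ties).

    Runs are clipped at stimulus onset before selection: temporal smoothing
    upstream is acausal and can drag the rising edge of a genuinely evoked
    run a frame or two before the stimulus, and the evoked window is a
    post-stimulus construct, so only the at/after-onset portion of a run
    counts.
    """
    supra = profile.p > profile.threshold
    runs = [
        (max(s, stim_onset_frame), e)
        for s, e in _runs_above(supra)
        if e > stim_onset_frame and (e - max(s, stim_onset_frame)) >= min_run
    ]
    if not runs:
        raise NoEvokedWindowError(
            "no evoked window: no supra-threshold P^event run of length "
            f">= {min_run} at or after frame {stim_onset_frame}"
        )
    start, end = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    return EvokedWindow(
        start_frame=int(start),
        end_frame=int(end),
        duration_ms=frames_to_ms(int(end - start), profile.frame_rate),
    )


def select_evoked_trials(raster: EventRaster, window: EvokedWindow) -> np.ndarray:
    """Indices of trials with at least one binary event inside the evoked
    window.  A neuron is responsive iff the result is non-empty."""
    if window.end_frame > raster.n_frames:
        raise ValidationError("evoked window exceeds the trial length")
    hit = raster.binary[window.start_frame : window.end_frame].any(axis=0)
    return np.nonzero(hit)[0]


def persistent_cells(responders_a, responders_b) -> set:
    """Cells responsive in both conditions: plain set intersection."""
    return set(responders_a) & set(responders_b)


def epsp_metrics(t_ms, v_mV, pulse_onset_ms: float) -> EpspMetrics:
    """EPSP amplitude and latency from one membrane-potential sweep.

    Amplitude: max of the post-pulse segment minus the mean of the 20 ms
    pre-pulse baseline.  Latency: delay from pulse onset to the first sample
    where the baseline-subtracted response exceeds 10% of its maximum.
    """
    t = np.asarray(t_ms, dtype=float).ravel()
    v = np.asarray(v_mV, dtype=float).ravel()
    if t.shape != v.shape:
        raise ValidationError("time and voltage arrays must match")
    base_mask = (t >= pulse_onset_ms - 20.0) & (t < pulse_onset_ms)
    if not base_mask.any() or t[base_mask].min() > pulse_onset_ms - 20.0 + 1e-9:
        raise ValidationError("need >= 20 ms of pre-pulse baseline samples")
    baseline = float(v[base_mask].mean())
    post = t >= pulse_onset_ms
    if not post.any():
        raise ValidationError("no post-pulse samples")
    amplitude = float(v[post].max() - baseline)
    if amplitude <= 0:
        return EpspMetrics(
            amplitude_mV=amplitude,
            latency_ms=None,
            flagged=True,
            notes="non-positive amplitude: latency undefined",
        )
    crossing = post & (v - baseline > 0.1 * amplitude)
    if not crossing.any():
        return EpspMetrics(
            amplitude_mV=amplitude,
            latency_ms=None,
            flagged=True,
            notes="response never exceeded 10% of its maximum",
        )
    latency = float(t[crossing][0] - pulse_onset_ms)
    return EpspMetrics(amplitude_mV=amplitude, latency_ms=latency)
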