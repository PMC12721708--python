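"""Raw fluorescence → ΔF/F, baseline noise and SNR.

Two recipes are implemented, mirroring the two imaging preparations:

* **S1 (barrel cortex)** — background subtraction (1st percentile of a
  neuropil-free background trace), artifact-frame interpolation, 51-point
  order-1 Savitzky–Golay smoothing of the whole-session trace, ΔF/F with F0
  equal to the 1st percentile of the smoothed trace (ROIs with F0 < 0 are
  rejected as sign-inverted), baseline noise σ as the 1st percentile of
  5 s sliding-window SDs, and SNR as P95(ΔF/F)/σ.

* **Cerebellar (Purkinje dendrites)** — per-trial F0 as the 20th percentile
  of that trial's raw trace, 5-frame centered moving-average smoothing, then
  subtraction of the mean of the 5 pre-stimulus frames from the whole trial.

An order-1 Savitzky–Golay filter on a symmetric window is identical to a
centered moving average, so both smoothers share one implementation with
shrink-fit (symmetrically truncated) edge windows.
"""

from __future__ import annotations

import numpy as np

from .core import DffSession, TrialTrace, n_frames, percentile
from .errors import ValidationError

__all__ = [
    "interpolate_artifact_frames",
    "subtract_background",
    "smooth_savgol",
    "dff_s1",
    "dff_cerebellar",
    "noise_sigma",
    "snr",
    "motion_correct_rigid",
]

SAVGOL_WINDOW = 51
SIGMA_WINDOW_S = 5.0
F0_PERCENTILE_S1 = 1.0
F0_PERCENTILE_CEREBELLAR = 20.0
PRE_STIM_BASELINE_FRAMES = 5


def interpolate_artifact_frames(trace: TrialTrace, artifact_frames) -> TrialTrace:
    """Replace each artifact frame by the mean of its two neighbors.

    ``artifact_frames`` may be a sequence of frame indices (applied to every
    trial) or of ``(frame, trial)`` pairs.  Artifact frames must be interior
    and non-adjacent so both neighbors are clean.
    """
    values = trace.values.copy()
    nf = trace.n_frames
    pairs = []
    for item in artifact_frames:
        if np.ndim(item) == 0:
            for tr in range(trace.n_trials):
                pairs.append((int(item), tr))
        else:
            f, tr = item
            pairs.append((int(f), int(tr)))
    frames_per_trial = {}
    for f, tr in pairs:
        if f <= 0 or f >= nf - 1:
            raise ValidationError(
                f"artifact frame {f} at trial edge has no two neighbors"
            )
        frames_per_trial.setdefault(tr, []).append(f)
    for tr, fs in frames_per_trial.items():
        fs = sorted(fs)
        for a, b in zip(fs, fs[1:]):
            if b - a == 1:
                raise ValidationError(
                    f"adjacent artifact frames {a},{b} cannot be interpolated"
                )
        for f in fs:
            values[f, tr] = 0.5 * (trace.values[f - 1, tr] + trace.values[f + 1, tr])
    return TrialTrace(
        values=values,
        frame_rate=trace.frame_rate,
        stim_onset_frame=trace.stim_onset_frame,
        roi_id=trace.roi_id,
        brain_area=trace.brain_area,
    )


def subtract_background(trace: TrialTrace, background_trace) -> TrialTrace:
    """Subtract the 1st percentile of a neuropil-free background trace
    (a single scalar) from every frame of every trial."""
    bg = np.asarray(background_trace, dtype=float)
    if bg.size == 0:
        raise ValidationError("background trace is empty")
    offset = float(percentile(bg, 1.0))
    return TrialTrace(
        values=trace.values - offset,
        frame_rate=trace.frame_rate,
        stim_onset_frame=trace.stim_onset_frame,
        roi_id=trace.roi_id,
        brain_area=trace.brain_area,
    )


def _moving_mean_shrink(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with symmetrically shrinking edge windows.

    Equivalent to an order-1 Savitzky–Golay filter of the same (odd) window
    in the interior; near the edges the half-window shrinks so the window
    stays symmetric (shrink-fit).  Lines are fixed points everywhere.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo = idx - h
    hi = idx + h + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_savgol(series, window: int = SAVGOL_WINDOW, order: int = 1) -> np.ndarray:
    """51-point order-1 Savitzky–Golay smoothing with shrink-fit edges."""
    series = np.asarray(series, dtype=float)
    if order != 1:
        raise ValidationError("only order-1 smoothing is defined for this recipe")
    if window % 2 != 1 or window < 3:
        raise ValidationError("window must be odd and >= 3")
    if series.size < window:
        raise ValidationError(
            f"series of length {series.size} shorter than window {window}"
        )
    return _moving_mean_shrink(series, window)


def dff_s1(trace: TrialTrace, window: int = SAVGOL_WINDOW) -> DffSession:
    """S1 recipe: smooth the whole-session trace, F0 = 1st percentile of the
    smoothed trace, ΔF/F = (smoothed − F0)/F0.  F0 < 0 → ROI rejected."""
    raw = trace.session_trace()
    smoothed = smooth_savgol(raw, window=window)
    f0 = float(percentile(smoothed, F0_PERCENTILE_S1))
    if f0 < 0:
        return DffSession(
            dff=None,
            f0=f0,
            frame_rate=trace.frame_rate,
            stim_onset_frame=trace.stim_onset_frame,
            roi_id=trace.roi_id,
            rejected=True,
            reject_reason="F0 < 0 after background subtraction (signal inversion)",
        )
    if f0 == 0:
        raise ValidationError("F0 == 0: ΔF/F undefined (division by zero)")
    dff = (smoothed - f0) / f0
    dff = dff.reshape(trace.n_frames, trace.n_trials, order="F")
    return DffSession(
        dff=dff,
        f0=f0,
        frame_rate=trace.frame_rate,
        stim_onset_frame=trace.stim_onset_frame,
        roi_id=trace.roi_id,
    )


def dff_cerebellar(trace: TrialTrace, smooth_frames: int = 5) -> DffSession:
    """Cerebellar recipe, applied per trial.

    F0 is the 20th percentile of the trial's raw trace; ΔF/F is low-pass
    filtered with a centered ``smooth_frames`` moving window; the mean of
    the 5 pre-stimulus frames is then subtracted from the whole trial, so
    the pre-stimulus baseline averages exactly zero.
    """
    if trace.stim_onset_frame < PRE_STIM_BASELINE_FRAMES:
        raise ValidationError(
            "need >= 5 pre-stimulus frames for baseline normalization"
        )
    out = np.empty_like(trace.values)
    f0s = np.empty(trace.n_trials)
    pre = slice(
        trace.stim_onset_frame - PRE_STIM_BASELINE_FRAMES, trace.stim_onset_frame
    )
    for tr in range(trace.n_trials):
        raw = trace.values[:, tr]
        f0 = float(percentile(raw, F0_PERCENTILE_CEREBELLAR))
        if f0 == 0:
            raise ValidationError(f"trial {tr}: F0 == 0, ΔF/F undefined")
        d = (raw - f0) / f0
        d = _moving_mean_shrink(d, smooth_frames)
        d = d - d[pre].mean()
        out[:, tr] = d
        f0s[tr] = f0
    return DffSession(
        dff=out,
        f0=f0s,
        frame_rate=trace.frame_rate,
        stim_onset_frame=trace.stim_onset_frame,
        roi_id=trace.roi_id,
    )


def noise_sigma(session: DffSession, window_s: float = SIGMA_WINDOW_S) -> float:
    """Baseline noise σ: 1st percentile of sliding-window (stride 1) sample
    SDs of the session ΔF/F trace.  5 s is 155 frames at 30.98 Hz."""
    x = session.session_trace()
    w = n_frames(window_s, session.frame_rate)
    if x.size < w:
        raise ValidationError(
            f"session of {x.size} frames shorter than the {w}-frame window"
        )
    n = x.size - w + 1
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x * x)])
    idx = np.arange(n)
    sums = csum[idx + w] - csum[idx]
    sums2 = csum2[idx + w] - csum2[idx]
    var = (sums2 - sums * sums / w) / (w - 1)
    sds = np.sqrt(np.maximum(var, 0.0))
    return float(percentile(sds, 1.0))


def snr(session: DffSession, sigma: float) -> float:
    """SNR: 95th percentile of all ΔF/F samples divided by σ."""
    if sigma <= 0:
        raise ValidationError("SNR undefined for sigma <= 0")
    return float(percentile(session.session_trace(), 95.0)) / sigma


def motion_correct_rigid(stack, reference=None, search_radius: int = 10):
    """Integer-pixel rigid registration by whole-frame cross-correlation.

    Each frame is registered to ``reference`` (default: the mean image) by
    the integer shift maximizing the normalized whole-frame circular
    cross-correlation, restricted to ``|dy|, |dx| <= search_radius``.  Ties
    are broken toward zero shift.  Returns ``(corrected_stack, shifts)``
    where ``shifts`` is an (n_frames, 2) array of estimated (dy, dx).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValidationError("stack must be a non-empty (frames, H, W) array")
    nf, H, W = stack.shape
    if reference is None:
        reference = stack.mean(axis=0)
    ref = reference - reference.mean()
    ref_norm = np.linalg.norm(ref)
    if ref_norm == 0:
        ref_norm = 1.0
    Fref = np.fft.rfft2(ref)
    dys = np.arange(-search_radius, search_radius + 1)
    dxs = np.arange(-search_radius, search_radius + 1)
    # candidate order: smallest |dy|+|dx| first, so argmax ties favor zero
    order = sorted(
        ((abs(dy) + abs(dx), dy, dx) for dy in dys for dx in dxs)
    )
    shifts = np.zeros((nf, 2), dtype=int)
    corrected = np.empty_like(stack)
    for i in range(nf):
        frame = stack[i] - stack[i].mean()
        norm = np.linalg.norm(frame)
        if norm == 0:
            norm = 1.0
        # circular cross-correlation surface via FFT
        surf = np.fft.irfft2(np.fft.rfft2(frame) * np.conj(Fref), s=(H, W))
        surf /= norm * ref_norm
        best = None
        for _, dy, dx in order:
            val = surf[dy % H, dx % W]
            if best is None or val > best[0] + 1e-12:
                best = (val, dy, dx)
        _, dy, dx = best
        shifts[i] = (dy, dx)
        corrected[i] = np.roll(stack[i], (-dy, -dx), axis=(0, 1))
    return corrected, shifts
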