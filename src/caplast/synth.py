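"""Ground-truthed synthetic inputs for every pipeline stage.

The calcium forward model is the one the analysis assumes: a latent AR(1)
"calcium" trace driven by impulses (spontaneous Poisson events plus at most
one stimulus-locked evoked event per trial), read out as fluorescence
``F[t] = baseline_f · (1 + c[t]) + ε[t]`` with additive Gaussian noise.
Evoked amplitudes in post-induction trials are multiplied by a plasticity
factor, which is the ground truth the plasticity stage must recover.

One master seed feeds independent per-purpose substreams (event placement,
latency jitter, readout noise), so changing the noise level never moves an
event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .core import TrialTrace, ms_to_frames
from .errors import ValidationError

__all__ = [
    "SynthSessionConfig",
    "GroundTruth",
    "ActivationDisc",
    "generate_calcium_session",
    "generate_motion_trace",
    "generate_reflectance_stack",
    "generate_epsp_sweep",
]


@dataclass
class SynthSessionConfig:
    """Parameters of the synthetic trial-based calcium session.

    Defaults follow the acquisition the analysis was designed for: 20 s
    trials at 30.98 Hz with one stimulus per trial, GCaMP6f-like decay
    (gamma ≈ exp(−Δt/τ) with τ ≈ 400 ms), sparse spontaneous transients and
    a reliable short-latency evoked response.
    """

    n_rois: int = 10
    n_trials_pre: int = 40
    n_trials_post: int = 40
    frames_per_trial: int = 620
    frame_rate: float = 30.98
    stim_onset_frame: int = 155
    gamma: float = 0.92
    spont_rate: float = 0.1
    evoked_prob: float = 0.8
    evoked_latency_ms: float = 50.0
    latency_jitter_ms: float = 30.0
    amp_mean: float = 0.5
    amp_sd: float = 0.1
    plasticity_factor: float = 1.0
    baseline_f: float = 100.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        numeric = {
            k: v for k, v in self.__dict__.items() if isinstance(v, (int, float))
        }
        for name, value in numeric.items():
            if not math.isfinite(value):
                raise ValidationError(f"config field {name!r} is not finite")
        for name in ("n_rois", "n_trials_pre", "n_trials_post", "frames_per_trial"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not 0.0 < self.gamma < 1.0:
            raise ValidationError("gamma must lie in (0, 1)")
        if not 0.0 <= self.evoked_prob <= 1.0:
            raise ValidationError("evoked_prob must lie in [0, 1]")
        if self.plasticity_factor <= 0:
            raise ValidationError("plasticity_factor must be positive")
        if self.spont_rate < 0 or self.noise_sd < 0 or self.amp_sd < 0:
            raise ValidationError("rates and SDs must be non-negative")
        if not 0 <= self.stim_onset_frame < self.frames_per_trial:
            raise ValidationError("stim_onset_frame must lie within the trial")

    @property
    def n_trials(self) -> int:
        return self.n_trials_pre + self.n_trials_post

    @property
    def trial_duration_s(self) -> float:
        return self.frames_per_trial / self.frame_rate


@dataclass
class ActivationDisc:
    """Circular activated region of a reflectance stack: centre (row, col)
    in pixels, radius in pixels, and fractional reflectance decrease."""

    center: tuple[float, float]
    radius: float
    depth: float


@dataclass
class GroundTruth:
    """Everything the generators know that the pipeline must recover."""

    # events[roi][trial] -> (n_events, 2) array of (frame, amplitude)
    events: list = field(default_factory=list)
    evoked_flags: np.ndarray | None = None     # (n_rois, n_trials) bool
    evoked_frames: np.ndarray | None = None    # (n_rois, n_trials), -1 = none
    trial_epoch: np.ndarray | None = None      # "pre"/"post" per trial
    trial_time_min: np.ndarray | None = None   # stimulus time within epoch, min
    movement_bouts: list = field(default_factory=list)
    true_plasticity_factor: float = 1.0
    activation_disc: ActivationDisc | None = None

    def n_events(self) -> int:
        return sum(ev.shape[0] for roi in self.events for ev in roi)


def _substreams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_calcium_session(config: SynthSessionConfig):
    """Simulate a session and return ``(list of TrialTrace, GroundTruth)``.

    Pre-induction trials come first (columns ``0 .. n_trials_pre-1``), then
    post-induction trials whose evoked amplitudes are scaled by
    ``plasticity_factor``.
    """
    cfg = config
    rng_events, rng_jitter, rng_noise = _substreams(cfg.seed, 3)

    p_frame = cfg.spont_rate / cfg.frame_rate
    traces: list[TrialTrace] = []
    truth = GroundTruth(true_plasticity_factor=cfg.plasticity_factor)
    truth.evoked_flags = np.zeros((cfg.n_rois, cfg.n_trials), dtype=bool)
    truth.evoked_frames = np.full((cfg.n_rois, cfg.n_trials), -1, dtype=int)
    truth.trial_epoch = np.array(
        ["pre"] * cfg.n_trials_pre + ["post"] * cfg.n_trials_post
    )
    # stimulus times, minutes from the start of each epoch
    within = np.concatenate(
        [np.arange(cfg.n_trials_pre), np.arange(cfg.n_trials_post)]
    )
    truth.trial_time_min = (
        within * cfg.trial_duration_s + cfg.stim_onset_frame / cfg.frame_rate
    ) / 60.0

    for roi in range(cfg.n_rois):
        F = np.empty((cfg.frames_per_trial, cfg.n_trials))
        roi_events = []
        for trial in range(cfg.n_trials):
            s = np.zeros(cfg.frames_per_trial)
            ev_list = []
            # spontaneous events: per-frame Poisson thinning of the rate
            counts = rng_events.poisson(p_frame, size=cfg.frames_per_trial)
            for f in np.nonzero(counts)[0]:
                for _ in range(counts[f]):
                    a = max(rng_events.normal(cfg.amp_mean, cfg.amp_sd), 0.0)
                    s[f] += a
                    ev_list.append((f, a))
            # at most one evoked event per trial
            has_evoked = rng_events.random() < cfg.evoked_prob
            jit = rng_jitter.uniform(-cfg.latency_jitter_ms, cfg.latency_jitter_ms)
            if has_evoked:
                lat_frames = ms_to_frames(cfg.evoked_latency_ms + jit, cfg.frame_rate)
                f_ev = cfg.stim_onset_frame + lat_frames
                if 0 <= f_ev < cfg.frames_per_trial:
                    a = max(rng_events.normal(cfg.amp_mean, cfg.amp_sd), 0.0)
                    if trial >= cfg.n_trials_pre:
                        a *= cfg.plasticity_factor
                    s[f_ev] += a
                    ev_list.append((f_ev, a))
                    truth.evoked_flags[roi, trial] = True
                    truth.evoked_frames[roi, trial] = f_ev
            # AR(1) recursion c[t] = gamma c[t-1] + s[t]
            c = lfilter([1.0], [1.0, -cfg.gamma], s)
            F[:, trial] = cfg.baseline_f * (1.0 + c)
            ev_list.sort()
            roi_events.append(
                np.array(ev_list, dtype=float).reshape(-1, 2)
            )
        F += rng_noise.normal(0.0, cfg.noise_sd, size=F.shape)
        traces.append(
            TrialTrace(
                values=F,
                frame_rate=cfg.frame_rate,
                stim_onset_frame=cfg.stim_onset_frame,
                roi_id=f"roi{roi}",
                brain_area="s1",
            )
        )
        truth.events.append(roi_events)
    return traces, truth


def _validate_bouts(bouts, n_frames):
    prev_end = -1
    out = []
    for start, end in sorted(bouts):
        if not (0 <= start < end <= n_frames):
            raise ValidationError(f"bout ({start}, {end}) outside [0, {n_frames})")
        if start < prev_end:
            raise ValidationError("movement bouts overlap")
        prev_end = end
        out.append((int(start), int(end)))
    return out


def generate_motion_trace(n_frames, bouts=None, n_bouts=5, max_len=30, seed=0):
    """Per-frame binary movement trace that is 1 exactly on bout frames.

    If ``bouts`` is None, ``n_bouts`` non-overlapping bouts of length
    1..max_len are sampled.  Returns ``(trace, bouts)`` with bouts sorted,
    half-open ``(start, end)``.
    """
    rng = np.random.default_rng(seed)
    if bouts is None:
        picked = []
        occupied = np.zeros(n_frames, dtype=bool)
        attempts = 0
        while len(picked) < n_bouts and attempts < 1000:
            attempts += 1
            length = int(rng.integers(1, max_len + 1))
            start = int(rng.integers(0, max(1, n_frames - length)))
            if occupied[start : start + length].any():
                continue
            occupied[start : start + length] = True
            picked.append((start, start + length))
        bouts = picked
    bouts = _validate_bouts(bouts, n_frames)
    trace = np.zeros(n_frames, dtype=bool)
    for start, end in bouts:
        trace[start:end] = True
    return trace, bouts


def generate_reflectance_stack(
    shape=(128, 128),
    n_trials=30,
    disc=ActivationDisc(center=(64.0, 64.0), radius=24.0, depth=0.03),
    noise_sd=0.0,
    seed=0,
    frame_rate=30.0,
    stim_onset_frame=30,
    n_frames=90,
    r0=100.0,
):
    """Reflectance image stack with a stimulus-evoked reflectance decrease.

    Pre-stimulus frames sit at ``r0``; from stimulus onset on, pixels inside
    the disc drop to ``r0 · (1 − depth)`` (deoxyhemoglobin darkening of the
    activated region).  Gaussian noise of SD ``noise_sd`` is added
    everywhere.  Returns ``(stack, GroundTruth)`` where stack is a
    (n_trials, n_frames, H, W) array.
    """
    H, W = shape
    cy, cx = disc.center
    if not (disc.radius <= cy <= H - 1 - disc.radius and disc.radius <= cx <= W - 1 - disc.radius):
        raise ValidationError("activation disc extends outside the image")
    if stim_onset_frame < 1 or stim_onset_frame >= n_frames:
        raise ValidationError("stim_onset_frame must lie within the stack")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:H, 0:W]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= disc.radius**2
    frame_pre = np.full((H, W), r0)
    frame_post = frame_pre.copy()
    frame_post[inside] = r0 * (1.0 - disc.depth)
    stack = np.empty((n_trials, n_frames, H, W))
    stack[:, :stim_onset_frame] = frame_pre
    stack[:, stim_onset_frame:] = frame_post
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
    truth = GroundTruth(activation_disc=disc)
    return stack, truth


def generate_epsp_sweep(
    amplitude_mV=5.0,
    onset_ms=50.0,
    rise_tau_ms=2.0,
    decay_tau_ms=20.0,
    baseline_mV=-65.0,
    noise_sd=0.0,
    rate_hz=10000.0,
    duration_ms=200.0,
    seed=0,
):
    """Membrane-potential sweep carrying one double-exponential EPSP.

    The EPSP kernel ``exp(−t/τ_d) − exp(−t/τ_r)`` is normalized so its peak
    equals ``amplitude_mV`` above baseline.  Requires at least 20 ms of
    pre-onset baseline (the baseline window of the amplitude measurement).
    Returns ``(t_ms, v_mV, truth)`` where truth records the analytic peak
    time and amplitude.
    """
    if onset_ms < 20.0:
        raise ValidationError("onset_ms must be >= 20 (baseline window unavailable)")
    if rise_tau_ms <= 0 or decay_tau_ms <= 0 or rise_tau_ms >= decay_tau_ms:
        raise ValidationError("need 0 < rise_tau_ms < decay_tau_ms")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_ms, 1000.0 / rate_hz)
    v = np.full_like(t, baseline_mV)
    dt = t - onset_ms
    on = dt >= 0
    kern = np.exp(-dt[on] / decay_tau_ms) - np.exp(-dt[on] / rise_tau_ms)
    # analytic peak of the double exponential
    t_peak = (
        rise_tau_ms
        * decay_tau_ms
        / (decay_tau_ms - rise_tau_ms)
        * math.log(decay_tau_ms / rise_tau_ms)
    )
    peak_val = math.exp(-t_peak / decay_tau_ms) - math.exp(-t_peak / rise_tau_ms)
    if amplitude_mV != 0:
        v[on] += amplitude_mV * kern / peak_val
    if noise_sd > 0:
        v += rng.normal(0.0, noise_sd, size=v.shape)
    truth = {
        "amplitude_mV": amplitude_mV,
        "onset_ms": onset_ms,
        "peak_time_ms": onset_ms + t_peak,
        "rise_tau_ms": rise_tau_ms,
        "decay_tau_ms": decay_tau_ms,
        "baseline_mV": baseline_mV,
    }
    return t, v, truth
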