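"""Sparse non-negative event inference under an AR(1) calcium kernel.

The calcium trace is modelled as ``c[t] = gamma·c[t−1] + s[t]`` with
non-negative event amplitudes ``s``.  ``oasis_ar1`` solves

    min_c ||c − y||²  s.t.  s[t] = c[t] − gamma·c[t−1] ∈ {0} ∪ [s_min, ∞)

by pool-adjacent-violators segment merging (the online active-set method,
AR(1) case): whenever the jump into the next pool falls short of the
minimum event amplitude, the pools are merged and the constrained segment
decays exactly by ``gamma`` per frame.  With ``s_min = 0`` this is the
exact non-negative solution; the event threshold used downstream is
``s_min = 3σ`` with σ the baseline noise of the ΔF/F trace.

``deconv_oracle`` solves the same problem (``s_min = 0``) by explicit
non-negative least squares on the lower-triangular impulse-response design
matrix; it is the independent check, O(T²) and capped at 500 frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .errors import ValidationError

__all__ = ["Ar1Model", "EventRaster", "estimate_gamma", "oasis_ar1", "deconv_oracle"]

GAMMA_BOUNDS = (0.5, 0.999)


@dataclass
class Ar1Model:
    """AR(1) kernel: per-frame decay ``gamma`` and minimum event amplitude
    ``s_min`` (ΔF/F units; 3σ in the standard pipeline)."""

    gamma: float
    s_min: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.gamma < 1.0:
            raise ValidationError("gamma must lie in (0, 1)")
        if self.s_min < 0:
            raise ValidationError("s_min must be non-negative")

    @classmethod
    def from_tau(cls, tau_s: float, frame_rate: float, s_min: float = 0.0):
        """Kernel from an indicator decay time constant τ (seconds):
        gamma = exp(−1/(τ·frame_rate))."""
        return cls(gamma=float(np.exp(-1.0 / (tau_s * frame_rate))), s_min=s_min)


@dataclass
class EventRaster:
    """Per-(frame, trial) inferred event amplitudes and their binarization.

    ``binary`` marks frames whose amplitude reaches the model's minimum
    event amplitude; a trial-frame contributes at most one event to any
    downstream count, however much amplitude mass it carries.
    """

    amplitudes: np.ndarray  # (frames, trials), >= 0
    binary: np.ndarray      # (frames, trials), bool
    s_min: float
    frame_rate: float
    stim_onset_frame: int

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.binary = np.asarray(self.binary, dtype=bool)
        if self.amplitudes.shape != self.binary.shape:
            raise ValidationError("amplitudes and binary must share a shape")
        if (self.amplitudes < -1e-12).any():
            raise ValidationError("amplitudes must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_trials(self) -> int:
        return self.amplitudes.shape[1]


def estimate_gamma(dff, frame_rate: float | None = None) -> float:
    """AR coefficient from the lag-2 / lag-1 autocovariance ratio.

    For an AR(1) signal plus white noise the autocovariance decays by gamma
    per lag from lag 1 on, while lag 0 is inflated by the noise variance, so
    acov(2)/acov(1) is noise-robust.  The estimate is clipped to
    (0.5, 0.999); hitting the lower bound (e.g. on white noise) is reported
    via the clipped value itself.
    """
    x = np.asarray(dff, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 100:
        raise ValidationError("need >= 100 frames to estimate gamma")
    x = x - x.mean()
    # pool lagged covariances within trials (columns) so trial boundaries
    # do not bias the estimate
    acov1 = float((x[1:] * x[:-1]).sum()) / x.size
    acov2 = float((x[2:] * x[:-2]).sum()) / x.size
    if acov1 == 0 or not np.isfinite(acov1) or not np.isfinite(acov2):
        raise ValidationError(
            "gamma estimate undefined (degenerate autocovariance); "
            "supply gamma explicitly or derive it from a decay constant "
            "via Ar1Model.from_tau"
        )
    g = acov2 / acov1
    return float(np.clip(g, *GAMMA_BOUNDS))


def _oasis_single(y: np.ndarray, gamma: float, s_min: float) -> np.ndarray:
    """AR(1) OASIS on one trace; returns the fitted calcium c (>= 0)."""
    T = y.size
    # pools: [value v, weight w, start t, length l]; c at pool start = v/w
    v = np.empty(T)
    w = np.empty(T)
    t0 = np.empty(T, dtype=int)
    ln = np.empty(T, dtype=int)
    # cache powers of gamma up to T
    gpow = np.power(gamma, np.arange(T + 1))
    m = 0
    for t in range(T):
        v[m] = y[t]
        w[m] = 1.0
        t0[m] = t
        ln[m] = 1
        m += 1
        while m > 1:
            i = m - 2
            # jump from the decayed end of pool i into pool i+1
            if v[m - 1] / w[m - 1] >= gamma ** ln[i] * (v[i] / w[i]) + s_min:
                break
            # merge pool i+1 into pool i
            g_l = gpow[ln[i]]
            v[i] += g_l * v[m - 1]
            w[i] += g_l * g_l * w[m - 1]
            ln[i] += ln[m - 1]
            m -= 1
    c = np.empty(T)
    for i in range(m):
        h = max(v[i] / w[i], 0.0)
        L = ln[i]
        c[t0[i] : t0[i] + L] = h * gpow[:L]
    return c


def oasis_ar1(
    dff, model: Ar1Model, frame_rate: float = np.nan, stim_onset_frame: int = 0
) -> EventRaster:
    """Thresholded AR(1) deconvolution of ΔF/F trial(s).

    ``dff`` may be 1-D (one trial) or (frames, trials).  Events with
    amplitude below ``model.s_min`` are disallowed by the solver itself (the
    merge condition re-absorbs their mass into the preceding segment), so
    every surviving event amplitude is ≥ s_min.
    """
    d = np.asarray(dff, dtype=float)
    if not np.isfinite(d).all():
        raise ValidationError("dff must be finite")
    one_d = d.ndim == 1
    if one_d:
        d = d[:, None]
    T, n_trials = d.shape
    amps = np.zeros_like(d)
    for tr in range(n_trials):
        c = _oasis_single(d[:, tr], model.gamma, model.s_min)
        s = np.empty(T)
        s[0] = c[0]
        s[1:] = c[1:] - model.gamma * c[:-1]
        s[np.abs(s) < 1e-10] = 0.0
        amps[:, tr] = np.maximum(s, 0.0)
    thresh = model.s_min if model.s_min > 0 else 1e-8
    binary = amps >= thresh - 1e-12
    return EventRaster(
        amplitudes=amps,
        binary=binary,
        s_min=model.s_min,
        frame_rate=frame_rate,
        stim_onset_frame=stim_onset_frame,
    )


def deconv_oracle(dff, gamma: float) -> np.ndarray:
    """Exact non-negative least-squares deconvolution of one trial.

    Builds the full lower-triangular design matrix ``K[i, j] = gamma^(i−j)``
    and solves ``min ||K s − y||, s >= 0``.  O(T²) memory; trials longer
    than 500 frames are refused.
    """
    y = np.asarray(dff, dtype=float).ravel()
    if y.size > 500:
        raise ValidationError("oracle limited to trials of <= 500 frames")
    if not 0.0 < gamma < 1.0:
        raise ValidationError("gamma must lie in (0, 1)")
    T = y.size
    i, j = np.indices((T, T))
    K = np.where(i >= j, gamma ** np.maximum(i - j, 0), 0.0)
    s, _ = nnls(K, y)
    return s
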