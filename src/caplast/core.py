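"""Core containers and numeric conventions.

All frame indices are 0-based and all frame windows are half-open.
Millisecond values are derived from frame counts, never stored as primary
keys.  The percentile convention used everywhere in the package is the
midpoint-anchored one (the p-th percentile of n points interpolates between
order statistics anchored at probabilities (k − 0.5)/n), which is numpy's
``method="hazen"`` and what MATLAB's ``prctile`` computes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ValidationError

__all__ = [
    "TrialTrace",
    "DffSession",
    "percentile",
    "n_frames",
    "ms_to_frames",
    "frames_to_ms",
]


def percentile(a, q):
    """Midpoint-anchored percentile of ``a`` at ``q`` (in percent).

    Equivalent to MATLAB ``prctile``: ranks are anchored at probabilities
    (k − 0.5)/n with linear interpolation between adjacent order statistics
    and clamping at the extremes.
    """
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValidationError("percentile of an empty array is undefined")
    return np.percentile(a, q, method="hazen")


def n_frames(duration_s: float, frame_rate: float) -> int:
    """Number of frames spanning ``duration_s`` seconds: round(T · rate).

    Reproduces the standard pairing of a 5 s window with 155 frames at
    30.98 Hz, and 1 s with 30 frames at 30 Hz.
    """
    return int(round(duration_s * frame_rate))


def ms_to_frames(duration_ms: float, frame_rate: float) -> int:
    return int(round(duration_ms / 1000.0 * frame_rate))


def frames_to_ms(count: int, frame_rate: float) -> int:
    """Duration in ms of ``count`` frames, rounded to the nearest ms."""
    return int(round(count / frame_rate * 1000.0))


@dataclass
class TrialTrace:
    """One ROI's raw fluorescence for one session.

    ``values`` is a (frames, trials) array; each column is one trial sampled
    at ``frame_rate`` with the stimulus delivered at ``stim_onset_frame``.
    """

    values: np.ndarray
    frame_rate: float
    stim_onset_frame: int
    roi_id: str = "roi0"
    brain_area: Literal["cerebellum", "s1"] = "s1"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a (frames, trials) array")
        if not (0 <= self.stim_onset_frame < self.n_frames):
            raise ValidationError(
                "stim_onset_frame must lie within the trial "
                f"(got {self.stim_onset_frame} for {self.n_frames} frames)"
            )
        if self.frame_rate <= 0 or not np.isfinite(self.frame_rate):
            raise ValidationError("frame_rate must be positive and finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    def session_trace(self) -> np.ndarray:
        """Trials concatenated in acquisition order into one 1-D series."""
        return self.values.ravel(order="F")


@dataclass
class DffSession:
    """ΔF/F traces for one ROI plus the scalars detection needs.

    ``sigma`` is the baseline noise (1st percentile of sliding-window SDs of
    ΔF/F) and ``snr`` the 95th percentile of ΔF/F divided by sigma; both are
    filled lazily by the preprocessing recipes that define them.  ``rejected``
    marks ROIs whose baseline F0 came out negative after background
    subtraction (signal inversion) and therefore carry no ΔF/F.
    """

    dff: np.ndarray | None
    f0: float | np.ndarray
    frame_rate: float
    stim_onset_frame: int
    roi_id: str = "roi0"
    sigma: float | None = None
    snr: float | None = None
    rejected: bool = False
    reject_reason: str = ""
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.dff is not None:
            self.dff = np.asarray(self.dff, dtype=float)
        if self.sigma is not None and self.sigma < 0:
            raise ValidationError("sigma must be non-negative")
        if not self.rejected and self.dff is None:
            raise ValidationError("non-rejected session must carry dff")

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]

    @property
    def n_trials(self) -> int:
        return self.dff.shape[1]

    def session_trace(self) -> np.ndarray:
        return self.dff.ravel(order="F")
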