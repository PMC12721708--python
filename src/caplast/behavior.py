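"""Movement detection and rest/active trial classification.

Raw behavior video reduces to a per-frame frame-difference energy series
(supplied by the caller); thresholding it yields a binary movement trace
sampled at the imaging frame rate.  A trial is a *rest* trial iff no
movement occurs within a guard window of at least 400 ms before and after
stimulus onset (inclusive at both ends); every other trial is *active*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ms_to_frames
from .errors import ValidationError

__all__ = ["MotionTrace", "motion_binary", "classify_trials"]


@dataclass
class MotionTrace:
    moving: np.ndarray  # bool per frame
    frame_rate: float

    def __post_init__(self):
        self.moving = np.asarray(self.moving, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.moving.size


def motion_binary(frame_diff_energy, threshold: float, frame_rate: float) -> MotionTrace:
    """Binary movement trace: moving where the consecutive-frame pixel
    difference energy exceeds ``threshold``.  Frame 0 has no predecessor and
    is defined non-moving."""
    e = np.asarray(frame_diff_energy, dtype=float).ravel()
    if (e < 0).any():
        raise ValidationError("frame-difference energies must be non-negative")
    moving = e > threshold
    if moving.size:
        moving[0] = False
    return MotionTrace(moving=moving, frame_rate=frame_rate)


def classify_trials(
    motion: MotionTrace,
    stim_onset_frames,
    frames_per_trial: int,
    guard_ms: float = 400.0,
) -> list[str]:
    """Label each trial ``"rest"`` / ``"active"`` (or ``"unclassifiable"``).

    ``stim_onset_frames`` are session-absolute stimulus frames, one per
    trial; the motion trace is sample-synchronous with imaging.  Rest
    requires no moving frame in [onset − g, onset + g] inclusive, with
    g = round(guard_ms · frame_rate / 1000); trials whose guard window
    leaves the trial bounds are flagged unclassifiable.
    """
    g = ms_to_frames(guard_ms, motion.frame_rate)
    labels = []
    onsets = np.asarray(stim_onset_frames, dtype=int)
    for i, onset in enumerate(onsets):
        trial_start = (onset // frames_per_trial) * frames_per_trial
        trial_end = trial_start + frames_per_trial
        lo, hi = onset - g, onset + g
        if lo < trial_start or hi >= trial_end or hi >= motion.n_frames:
            labels.append("unclassifiable")
            continue
        labels.append("active" if motion.moving[lo : hi + 1].any() else "rest")
    return labels
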