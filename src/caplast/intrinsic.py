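"""Intrinsic-signal activation mapping.

Reflectance stacks are Gaussian-smoothed and 4× block-mean downsampled.
Per trial, the baseline image R0 is the mean of the 1 s (30-frame at 30 Hz)
pre-stimulus period; post-stimulus frames are averaged in three 200 ms bins
(400–600, 600–800, 800–1000 ms after onset), each expressed as
ΔR/R = (bin − R0)/R0, and summed into one stimulus-evoked image.  Activated
cortex darkens (deoxyhemoglobin), so activation is ΔR/R below a z-score of
−1.5, z-scored over in-mask pixels of the trial-averaged image; a 5×5
median filter suppresses speckle before pixels are counted, and the area is
normalized by the cranial-window mask area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter
from skimage.measure import block_reduce

from .core import ms_to_frames, n_frames
from .errors import ValidationError

__all__ = [
    "ReflectanceStack",
    "ActivationMap",
    "preprocess_stack",
    "drr_trial",
    "activation_map",
]

DOWNSAMPLE = 4
BASELINE_S = 1.0
BIN_EDGES_MS = (400.0, 600.0, 800.0, 1000.0)
Z_CUT = -1.5
MEDIAN_SIZE = 5
MIN_TRIALS = 30


@dataclass
class ReflectanceStack:
    """(trials, frames, H, W) reflectance images with the cranial-window
    ROI mask."""

    frames: np.ndarray
    frame_rate: float
    stim_onset_frame: int
    window_mask: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.window_mask = np.asarray(self.window_mask, dtype=bool)
        if self.frames.ndim != 4:
            raise ValidationError("frames must be (trials, frames, H, W)")
        if self.window_mask.shape != self.frames.shape[2:]:
            raise ValidationError("mask geometry must match the images")
        if not self.window_mask.any():
            raise ValidationError("cranial-window mask is empty")

    @property
    def n_trials(self) -> int:
        return self.frames.shape[0]


@dataclass
class ActivationMap:
    drr: np.ndarray          # trial-mean summed ΔR/R image, zero outside mask
    zmap: np.ndarray         # z-scored over in-mask pixels
    binary_raw: np.ndarray   # z < -1.5 within mask, before median filtering
    binary: np.ndarray       # after 5×5 median filtering
    area_px: int
    area_norm: float
    area_px_raw: int

    def __post_init__(self):
        if not 0.0 <= self.area_norm <= 1.0:
            raise ValidationError("area_norm must lie in [0, 1]")


def preprocess_stack(
    stack: ReflectanceStack, gaussian_sigma: float = 1.0, factor: int = DOWNSAMPLE
) -> ReflectanceStack:
    """Gaussian smoothing (spatial, σ in pixels) then ``factor``× block-mean
    downsampling; the mask is downsampled by majority vote."""
    H, W = stack.frames.shape[2:]
    if H < 2 * factor or W < 2 * factor:
        raise ValidationError("image too small to downsample")
    Hc, Wc = (H // factor) * factor, (W // factor) * factor
    imgs = stack.frames[:, :, :Hc, :Wc]
    if gaussian_sigma > 0:
        imgs = gaussian_filter(imgs, sigma=(0, 0, gaussian_sigma, gaussian_sigma))
    ds = block_reduce(imgs, (1, 1, factor, factor), np.mean)
    mask = (
        block_reduce(
            stack.window_mask[:Hc, :Wc].astype(float), (factor, factor), np.mean
        )
        > 0.5
    )
    return ReflectanceStack(
        frames=ds,
        frame_rate=stack.frame_rate,
        stim_onset_frame=stack.stim_onset_frame,
        window_mask=mask,
    )


def drr_trial(stack: ReflectanceStack, trial: int) -> np.ndarray:
    """Summed stimulus-evoked ΔR/R image of one trial (three 200 ms bins)."""
    onset = stack.stim_onset_frame
    base_frames = n_frames(BASELINE_S, stack.frame_rate)
    if onset < base_frames:
        raise ValidationError(
            f"need {base_frames} pre-stimulus frames, have {onset}"
        )
    imgs = stack.frames[trial]
    r0 = imgs[onset - base_frames : onset].mean(axis=0)
    if (r0[stack.window_mask] <= 0).any():
        raise ValidationError("R0 <= 0 inside the mask: ΔR/R undefined")
    total = np.zeros_like(r0)
    for lo_ms, hi_ms in zip(BIN_EDGES_MS[:-1], BIN_EDGES_MS[1:]):
        lo = onset + ms_to_frames(lo_ms, stack.frame_rate)
        hi = onset + ms_to_frames(hi_ms, stack.frame_rate)
        if hi > imgs.shape[0]:
            raise ValidationError("post-stimulus bin exceeds the trial")
        bin_mean = imgs[lo:hi].mean(axis=0)
        total += (bin_mean - r0) / r0
    return total


def activation_map(
    trial_images,
    mask: np.ndarray,
    min_trials: int = MIN_TRIALS,
    z_cut: float = Z_CUT,
    median_size: int = MEDIAN_SIZE,
) -> ActivationMap:
    """Trial-averaged activation map with z-thresholding and area counts.

    ``trial_images`` is a (trials, H, W) array (or list) of summed ΔR/R
    images.  z-scores use the mean and SD of in-mask pixels only; the
    binary map keeps in-mask pixels with z below ``z_cut`` and is median
    filtered (``median_size``², zero-padded boundary) before counting.
    """
    imgs = np.asarray(trial_images, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if imgs.ndim != 3:
        raise ValidationError("trial_images must be (trials, H, W)")
    if imgs.shape[0] < min_trials:
        raise ValidationError(
            f"need >= {min_trials} trials, have {imgs.shape[0]}"
        )
    if not mask.any():
        raise ValidationError("cranial-window mask is empty")
    drr = imgs.mean(axis=0)
    drr = np.where(mask, drr, 0.0)
    inside = drr[mask]
    mu, sd = float(inside.mean()), float(inside.std(ddof=0))
    if sd == 0:
        raise ValidationError("degenerate z-map: zero variance inside mask")
    zmap = np.where(mask, (drr - mu) / sd, 0.0)
    binary_raw = mask & (zmap < z_cut)
    filtered = median_filter(
        binary_raw.astype(np.uint8), size=median_size, mode="constant", cval=0
    ).astype(bool)
    filtered &= mask
    mask_area = int(mask.sum())
    return ActivationMap(
        drr=drr,
        zmap=zmap,
        binary_raw=binary_raw,
        binary=filtered,
        area_px=int(filtered.sum()),
        area_norm=float(filtered.sum() / mask_area),
        area_px_raw=int(binary_raw.sum()),
    )
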