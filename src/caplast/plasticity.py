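"""Evoked-response quantification and pre/post plasticity comparison.

AUC over a post-stimulus window is defined as the mean ΔF/F over the
window's frames multiplied by the window duration in seconds (so AUC is
directly proportional to the mean response).  Amplitude is the maximum
ΔF/F in the same window.  Named window presets: ``default`` 0–700 ms,
``late`` 650–850 ms, ``sst_dreadd`` 0–1750 ms after stimulus onset.

Plasticity is quantified per neuron on trial-averaged responses of the
responsive trials of each epoch (pre: up to 50 min before induction; post:
up to 60 min after), restricted to persistent cells — neurons with evoked
events in both epochs.  Mouse-level statistics divide each mouse's
condition mean by its baseline mean and test the ratios against 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "ResponseWindow",
    "auc",
    "amplitude",
    "quantify_plasticity",
    "time_binned_auc",
    "normalize_by_mouse",
]


@dataclass(frozen=True)
class ResponseWindow:
    """Post-stimulus response window in ms relative to stimulus onset."""

    start_ms: float = 0.0
    end_ms: float = 700.0

    def __post_init__(self):
        if self.end_ms <= self.start_ms:
            raise ValidationError("end_ms must exceed start_ms")

    @classmethod
    def preset(cls, name: str) -> "ResponseWindow":
        presets = {
            "default": cls(0.0, 700.0),
            "late": cls(650.0, 850.0),
            "sst_dreadd": cls(0.0, 1750.0),
        }
        if name not in presets:
            raise ValidationError(f"unknown window preset {name!r}")
        return presets[name]

    @property
    def duration_s(self) -> float:
        return (self.end_ms - self.start_ms) / 1000.0

    def frames(self, stim_onset_frame: int, frame_rate: float, n_frames: int):
        """Frame indices f with start_ms <= (f − onset)/rate·1000 < end_ms."""
        last_needed = stim_onset_frame + int(np.ceil(self.end_ms * frame_rate / 1000.0)) - 1
        if last_needed >= n_frames:
            raise ValidationError("response window exceeds the trial length")
        f = np.arange(n_frames)
        t_ms = (f - stim_onset_frame) / frame_rate * 1000.0
        mask = (t_ms >= self.start_ms) & (t_ms < self.end_ms)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValidationError("response window lies outside the trial")
        return idx


def _window_frames(trace, window, stim_onset_frame, frame_rate):
    trace = np.asarray(trace, dtype=float).ravel()
    idx = window.frames(stim_onset_frame, frame_rate, trace.size)
    if idx[-1] >= trace.size:
        raise ValidationError("response window exceeds the trial length")
    return trace, idx


def auc(trace, window: ResponseWindow, stim_onset_frame: int, frame_rate: float) -> float:
    """AUC of a trial-averaged ΔF/F trace: mean over the window × duration
    (ΔF/F·s)."""
    trace, idx = _window_frames(trace, window, stim_onset_frame, frame_rate)
    return float(trace[idx].mean() * window.duration_s)


def amplitude(
    trace, window: ResponseWindow, stim_onset_frame: int, frame_rate: float
) -> float:
    """Maximum ΔF/F of a trial-averaged trace within the window."""
    trace, idx = _window_frames(trace, window, stim_onset_frame, frame_rate)
    return float(trace[idx].max())


@dataclass
class NeuronEpochs:
    """Per-neuron input to plasticity quantification: ΔF/F arrays
    (frames, trials) and responsive-trial indices for each epoch."""

    neuron_id: str
    mouse_id: str
    dff_pre: np.ndarray
    dff_post: np.ndarray
    trials_pre: np.ndarray
    trials_post: np.ndarray


def quantify_plasticity(
    neurons: list[NeuronEpochs],
    window: ResponseWindow,
    stim_onset_frame: int,
    frame_rate: float,
) -> pd.DataFrame:
    """Per-neuron pre/post AUC and amplitude on trial-averaged responsive
    trials.  Neurons without responsive trials in either epoch (non-
    persistent cells) are excluded.  Returns a tidy DataFrame with one row
    per retained neuron.
    """
    rows = []
    for nrn in neurons:
        if len(nrn.trials_pre) == 0 or len(nrn.trials_post) == 0:
            continue  # not a persistent cell
        mean_pre = np.asarray(nrn.dff_pre)[:, nrn.trials_pre].mean(axis=1)
        mean_post = np.asarray(nrn.dff_post)[:, nrn.trials_post].mean(axis=1)
        rows.append(
            {
                "neuron_id": nrn.neuron_id,
                "mouse_id": nrn.mouse_id,
                "auc_pre": auc(mean_pre, window, stim_onset_frame, frame_rate),
                "auc_post": auc(mean_post, window, stim_onset_frame, frame_rate),
                "amp_pre": amplitude(mean_pre, window, stim_onset_frame, frame_rate),
                "amp_post": amplitude(mean_post, window, stim_onset_frame, frame_rate),
                "n_trials_pre": int(len(nrn.trials_pre)),
                "n_trials_post": int(len(nrn.trials_post)),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "neuron_id",
            "mouse_id",
            "auc_pre",
            "auc_post",
            "amp_pre",
            "amp_post",
            "n_trials_pre",
            "n_trials_post",
        ],
    )
    if len(table):
        table["auc_ratio"] = table["auc_post"] / table["auc_pre"]
        table["amp_ratio"] = table["amp_post"] / table["amp_pre"]
    return table


def time_binned_auc(
    dff_by_neuron: dict,
    trial_times_min: np.ndarray,
    window: ResponseWindow,
    stim_onset_frame: int,
    frame_rate: float,
    bin_min: float = 10.0,
    n_bins: int | None = None,
) -> pd.Series:
    """Across-neuron mean AUC in 10-min bins of post-induction time.

    Trials are assigned to half-open bins [0, 10), [10, 20), ... by their
    stimulus time; within each cell, trials in a bin are averaged before the
    AUC is computed, then cells are averaged.  Empty bins are NaN.
    """
    t = np.asarray(trial_times_min, dtype=float)
    if n_bins is None:
        n_bins = int(np.floor(t.max() / bin_min)) + 1
    bin_of = np.floor(t / bin_min).astype(int)
    per_bin = {}
    for b in range(n_bins):
        in_bin = np.nonzero(bin_of == b)[0]
        if in_bin.size == 0:
            per_bin[b] = np.nan
            continue
        cell_aucs = []
        for dff in dff_by_neuron.values():
            mean_trace = np.asarray(dff)[:, in_bin].mean(axis=1)
            cell_aucs.append(auc(mean_trace, window, stim_onset_frame, frame_rate))
        per_bin[b] = float(np.mean(cell_aucs))
    idx = pd.Index(
        [f"{int(b * bin_min)}-{int((b + 1) * bin_min)} min" for b in per_bin],
        name="bin",
    )
    return pd.Series(list(per_bin.values()), index=idx, name="mean_auc")


def normalize_by_mouse(condition_means, baseline_means):
    """Per-mouse condition/baseline ratios with a one-sample t-test vs 1.

    Mice with a zero baseline are excluded (and counted in the result).
    Returns a dict with the ratios, t statistic, p-value and exclusions;
    with fewer than 2 usable mice or zero ratio variance the test is
    undefined and flagged.
    """
    cond = np.asarray(condition_means, dtype=float)
    base = np.asarray(baseline_means, dtype=float)
    if cond.shape != base.shape:
        raise ValidationError("condition and baseline must be paired per mouse")
    usable = base != 0
    n_excluded = int((~usable).sum())
    ratios = cond[usable] / base[usable]
    out = {
        "ratios": ratios,
        "n": int(ratios.size),
        "n_excluded": n_excluded,
        "t": np.nan,
        "p": np.nan,
        "flagged": False,
        "notes": "",
    }
    if ratios.size < 2:
        out["flagged"] = True
        out["notes"] = "fewer than 2 mice: test undefined"
        return out
    if np.allclose(ratios, ratios[0]):
        if np.allclose(ratios, 1.0):
            out["t"], out["p"] = 0.0, 1.0
        else:
            out["flagged"] = True
            out["notes"] = "zero variance in ratios: test undefined"
        return out
    t, p = sps.ttest_1samp(ratios, popmean=1.0)
    out["t"], out["p"] = float(t), float(p)
    return out
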