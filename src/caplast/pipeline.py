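"""End-to-end orchestration: simulate → preprocess → deconvolve → detect →
quantify, writing every intermediate plus a manifest of parameters, seeds
and per-stage checksums.

The evoked window is a population quantity: the binary rasters of all ROIs
are pooled along the trial axis before P^event is computed, and the one
window is then applied to every ROI to select its responsive trials.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import io as cio
from .behavior import classify_trials, motion_binary
from .core import DffSession
from .deconv import Ar1Model, EventRaster, oasis_ar1
from .errors import CaplastError, NoEvokedWindowError
from .events import (
    compute_pevent,
    evoked_window,
    exclude_edge_frames,
    select_evoked_trials,
)
from .plasticity import NeuronEpochs, ResponseWindow, quantify_plasticity
from .preprocess import dff_cerebellar, dff_s1, noise_sigma, snr
from .stats import select_and_run
from .synth import SynthSessionConfig, generate_calcium_session

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    synth: SynthSessionConfig = field(default_factory=SynthSessionConfig)
    recipe: str = "s1"
    window: ResponseWindow = field(default_factory=ResponseWindow)
    sigma_mult: float = 3.0
    gamma: float | None = None          # None: use the generator's gamma
    guard_ms: float = 400.0
    alpha: float = 0.05
    min_run: int = 1
    edge_exclude: int = 2  # smoothing half-window; trial-edge filter transients
    out_dir: str = "caplast_out"


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_fail(stage, exc):
    raise CaplastError(f"stage {stage!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the synthetic end-to-end pipeline; returns the artifact directory."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "parameters": {
            "recipe": cfg.recipe,
            "window_ms": [cfg.window.start_ms, cfg.window.end_ms],
            "sigma_mult": cfg.sigma_mult,
            "guard_ms": cfg.guard_ms,
            "alpha": cfg.alpha,
            "min_run": cfg.min_run,
            "seed": cfg.synth.seed,
            "synth": {k: v for k, v in cfg.synth.__dict__.items()},
        },
        "stages": {},
    }

    # --- simulate -----------------------------------------------------
    traces, truth = generate_calcium_session(cfg.synth)
    session_path = out / "session.h5"
    cio.write_session(session_path, traces)
    manifest["stages"]["simulate"] = {
        "file": session_path.name,
        "sha256": _checksum(session_path),
        "n_rois": len(traces),
        "n_trials": traces[0].n_trials,
    }

    # --- preprocess ---------------------------------------------------
    recipe = {"s1": dff_s1, "cerebellar": dff_cerebellar}.get(cfg.recipe)
    if recipe is None:
        raise CaplastError(f"stage 'preprocess' failed: unknown recipe {cfg.recipe!r}")
    sessions: dict[str, DffSession] = {}
    rejected = []
    for tr in traces:
        try:
            sess = recipe(tr)
        except CaplastError as exc:
            _stage_fail(f"preprocess (ROI {tr.roi_id})", exc)
        if sess.rejected:
            rejected.append(tr.roi_id)
            continue
        sess.sigma = noise_sigma(sess)
        if sess.sigma > 0:
            sess.snr = snr(sess, sess.sigma)
        sessions[tr.roi_id] = sess
    dff_path = out / "dff.h5"
    with h5py.File(dff_path, "w") as h5:
        h5.attrs["frame_rate"] = traces[0].frame_rate
        h5.attrs["stim_onset_frame"] = traces[0].stim_onset_frame
        for roi_id, sess in sessions.items():
            g = h5.create_group(roi_id)
            g.create_dataset("dff", data=sess.dff)
            g.attrs["f0"] = sess.f0
            g.attrs["sigma"] = sess.sigma
            g.attrs["snr"] = np.nan if sess.snr is None else sess.snr
    manifest["stages"]["preprocess"] = {
        "file": dff_path.name,
        "sha256": _checksum(dff_path),
        "rejected_rois": rejected,
    }

    # --- deconvolve ---------------------------------------------------
    gamma = cfg.synth.gamma if cfg.gamma is None else cfg.gamma
    rasters: dict[str, EventRaster] = {}
    for roi_id, sess in sessions.items():
        model = Ar1Model(gamma=gamma, s_min=cfg.sigma_mult * sess.sigma)
        rasters[roi_id] = oasis_ar1(
            sess.dff,
            model,
            frame_rate=sess.frame_rate,
            stim_onset_frame=sess.stim_onset_frame,
        )
    events_path = out / "events.h5"
    cio.write_raster(events_path, rasters)
    manifest["stages"]["deconv"] = {
        "file": events_path.name,
        "sha256": _checksum(events_path),
        "gamma": gamma,
    }

    # --- detect: population P^event and the evoked window -------------
    rasters = {
        roi_id: exclude_edge_frames(r, cfg.edge_exclude)
        for roi_id, r in rasters.items()
    }
    pooled = EventRaster(
        amplitudes=np.concatenate([r.amplitudes for r in rasters.values()], axis=1),
        binary=np.concatenate([r.binary for r in rasters.values()], axis=1),
        s_min=0.0,
        frame_rate=traces[0].frame_rate,
        stim_onset_frame=traces[0].stim_onset_frame,
    )
    profile = compute_pevent(pooled)
    try:
        window = evoked_window(profile, pooled.stim_onset_frame, min_run=cfg.min_run)
    except NoEvokedWindowError as exc:
        _stage_fail("detect", exc)
    responsive = {
        roi_id: select_evoked_trials(r, window) for roi_id, r in rasters.items()
    }
    detections_path = out / "detections.json"
    cio.write_json(
        detections_path,
        {
            "pevent": profile.p,
            "threshold": profile.threshold,
            "window_frames": [window.start_frame, window.end_frame],
            "window_ms": window.duration_ms,
            "responsive_trials": {k: v for k, v in responsive.items()},
        },
    )
    manifest["stages"]["detect"] = {
        "file": detections_path.name,
        "sha256": _checksum(detections_path),
        "window_ms": window.duration_ms,
    }

    # --- plasticity ---------------------------------------------------
    n_pre = cfg.synth.n_trials_pre
    table = _plasticity_table(sessions, responsive, n_pre, cfg, subset=None)
    plast_path = out / "plasticity.csv"
    table.to_csv(plast_path, index=False)
    manifest["stages"]["plasticity"] = {
        "file": plast_path.name,
        "sha256": _checksum(plast_path),
        "n_persistent": int(len(table)),
    }

    # --- rest-trial filter (synthetic movement-free session: all rest)
    motion = motion_binary(
        np.zeros(traces[0].n_frames * traces[0].n_trials),
        threshold=0.5,
        frame_rate=traces[0].frame_rate,
    )
    onsets = (
        np.arange(traces[0].n_trials) * traces[0].n_frames
        + traces[0].stim_onset_frame
    )
    labels = classify_trials(motion, onsets, traces[0].n_frames, cfg.guard_ms)
    rest = np.array([lab == "rest" for lab in labels])
    table_rest = _plasticity_table(sessions, responsive, n_pre, cfg, subset=rest)
    rest_path = out / "plasticity_rest.csv"
    table_rest.to_csv(rest_path, index=False)
    manifest["stages"]["behavior"] = {
        "file": rest_path.name,
        "sha256": _checksum(rest_path),
        "n_rest_trials": int(rest.sum()),
    }

    # --- stats: paired pre/post comparison over persistent cells ------
    if len(table) >= 4:
        decision = select_and_run(
            "paired", table["auc_post"], table["auc_pre"], alpha=cfg.alpha
        )
        manifest["stages"]["stats"] = {
            "test": decision.chosen_test,
            "statistic": decision.statistic,
            "p_value": decision.p_value,
            "label": decision.label,
        }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _plasticity_table(sessions, responsive, n_pre, cfg, subset=None):
    neurons = []
    for roi_id, sess in sessions.items():
        sel = responsive[roi_id]
        if subset is not None:
            sel = np.array([t for t in sel if subset[t]], dtype=int)
        sel_pre = np.array([t for t in sel if t < n_pre], dtype=int)
        sel_post = np.array([t - n_pre for t in sel if t >= n_pre], dtype=int)
        neurons.append(
            NeuronEpochs(
                neuron_id=roi_id,
                mouse_id="m0",
                dff_pre=sess.dff[:, :n_pre],
                dff_post=sess.dff[:, n_pre:],
                trials_pre=sel_pre,
                trials_post=sel_post,
            )
        )
    return quantify_plasticity(
        neurons,
        cfg.window,
        sessions[next(iter(sessions))].stim_onset_frame,
        sessions[next(iter(sessions))].frame_rate,
    )
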