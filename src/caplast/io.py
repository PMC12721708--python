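"""File formats: HDF5 sessions and event rasters, CSV traces, TIFF stacks.

HDF5 session layout: one group per ROI (``rois/<roi_id>``) holding a
``values`` dataset of shape (frames, trials); ``frame_rate`` and
``stim_onset_frame`` are root attributes shared by all ROIs.  Missing
attributes raise :class:`~caplast.errors.SchemaError` naming the field.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import TrialTrace
from .deconv import EventRaster
from .errors import SchemaError

__all__ = [
    "write_session",
    "read_session",
    "write_raster",
    "read_raster",
    "session_to_csv",
    "session_from_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_json",
]


def write_session(path, traces: list[TrialTrace]) -> None:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.attrs["frame_rate"] = traces[0].frame_rate
        h5.attrs["stim_onset_frame"] = traces[0].stim_onset_frame
        rois = h5.create_group("rois")
        for tr in traces:
            g = rois.create_group(tr.roi_id)
            g.create_dataset("values", data=tr.values)
            g.attrs["brain_area"] = tr.brain_area


def read_session(path) -> list[TrialTrace]:
    try:
        h5 = h5py.File(path, "r")
    except OSError as exc:
        raise SchemaError("file", f"not a readable HDF5 session: {path}") from exc
    with h5:
        for attr in ("frame_rate", "stim_onset_frame"):
            if attr not in h5.attrs:
                raise SchemaError(attr)
        if "rois" not in h5:
            raise SchemaError("rois")
        traces = []
        for roi_id, g in h5["rois"].items():
            if "values" not in g:
                raise SchemaError("values", f"ROI {roi_id!r} has no values dataset")
            traces.append(
                TrialTrace(
                    values=g["values"][()],
                    frame_rate=float(h5.attrs["frame_rate"]),
                    stim_onset_frame=int(h5.attrs["stim_onset_frame"]),
                    roi_id=roi_id,
                    brain_area=g.attrs.get("brain_area", "s1"),
                )
            )
    return traces


def write_raster(path, rasters: dict[str, EventRaster]) -> None:
    with h5py.File(path, "w") as h5:
        for roi_id, r in rasters.items():
            g = h5.create_group(roi_id)
            g.create_dataset("amplitudes", data=r.amplitudes)
            g.create_dataset("binary", data=r.binary.astype(np.uint8))
            g.attrs["s_min"] = r.s_min
            g.attrs["frame_rate"] = r.frame_rate
            g.attrs["stim_onset_frame"] = r.stim_onset_frame


def read_raster(path) -> dict[str, EventRaster]:
    out = {}
    with h5py.File(path, "r") as h5:
        for roi_id, g in h5.items():
            for name in ("amplitudes", "binary"):
                if name not in g:
                    raise SchemaError(name, f"ROI {roi_id!r} missing {name}")
            out[roi_id] = EventRaster(
                amplitudes=g["amplitudes"][()],
                binary=g["binary"][()].astype(bool),
                s_min=float(g.attrs.get("s_min", 0.0)),
                frame_rate=float(g.attrs.get("frame_rate", np.nan)),
                stim_onset_frame=int(g.attrs.get("stim_onset_frame", 0)),
            )
    return out


def session_to_csv(path, trace: TrialTrace) -> None:
    """Long-format per-ROI CSV: columns frame, trial, F."""
    nf, nt = trace.values.shape
    frames = np.tile(np.arange(nf), nt)
    trials = np.repeat(np.arange(nt), nf)
    pd.DataFrame(
        {"frame": frames, "trial": trials, "F": trace.values.ravel(order="F")}
    ).to_csv(path, index=False)


def session_from_csv(path, frame_rate: float, stim_onset_frame: int,
                     roi_id: str = "roi0") -> TrialTrace:
    df = pd.read_csv(path)
    for col in ("frame", "trial", "F"):
        if col not in df.columns:
            raise SchemaError(col)
    nf = int(df["frame"].max()) + 1
    nt = int(df["trial"].max()) + 1
    values = np.full((nf, nt), np.nan)
    values[df["frame"].to_numpy(), df["trial"].to_numpy()] = df["F"].to_numpy()
    return TrialTrace(
        values=values,
        frame_rate=frame_rate,
        stim_onset_frame=stim_onset_frame,
        roi_id=roi_id,
    )


def write_stack_tiff(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
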