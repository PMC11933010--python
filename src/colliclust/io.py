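"""HDF5 session store and validation.

Layout (one dataset per stimulus, ROIs stacked on the first axis):

    /raw/<stimulus>        (n_roi, n_time, n_rep) float32
    /neuropil/<stimulus>   (n_roi, n_time, n_rep) float32
    /anatomy/<column>      per-ROI anatomical columns (x, y, depth, ...)
    /ground_truth/<column> planted-truth columns

Stimulus timing lives both in each dataset's ``schedule`` attribute and in
a sidecar JSON manifest (``<store>.manifest.json``).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import SessionConfig
from .synthgen import Session, StimulusBlock

_ANATOMY_COLS = ("roi_id", "x_um", "y_um", "depth_um", "genotype",
                 "diameter_um")


def save_session(session: Session, path: str | Path) -> None:
    path = Path(path)
    gt = session.ground_truth
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(dataclasses.asdict(session.config))
        raw = f.create_group("raw")
        npil = f.create_group("neuropil")
        for name, block in session.blocks.items():
            d = raw.create_dataset(name, data=block.traces,
                                   compression="gzip", compression_opts=1)
            d.attrs["schedule"] = json.dumps(block.schedule)
            d.attrs["frame_rate"] = block.frame_rate
            npil.create_dataset(name, data=block.neuropil,
                                compression="gzip", compression_opts=1)
        for group_name, cols in [("anatomy", _ANATOMY_COLS),
                                 ("ground_truth", list(gt.columns))]:
            g = f.create_group(group_name)
            for col in cols:
                vals = gt[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)
    manifest = {
        "n_rois": session.n_rois,
        "stimuli": {name: {"schedule": block.schedule,
                           "frame_rate": block.frame_rate,
                           "shape": list(block.traces.shape)}
                    for name, block in session.blocks.items()},
    }
    Path(str(path) + ".manifest.json").write_text(
        json.dumps(manifest, indent=1, default=float))


def load_session(path: str | Path) -> Session:
    path = Path(path)
    blocks: dict[str, StimulusBlock] = {}
    with h5py.File(path, "r") as f:
        config = SessionConfig(**json.loads(f.attrs["config"]))
        for name in f["raw"]:
            d = f["raw"][name]
            blocks[name] = StimulusBlock(
                name=name, traces=d[...], neuropil=f["neuropil"][name][...],
                frame_rate=float(d.attrs["frame_rate"]),
                schedule=json.loads(d.attrs["schedule"]),
            )
        gt = {}
        for col in f["ground_truth"]:
            vals = f["ground_truth"][col][...]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            gt[col] = vals
    return Session(blocks=blocks, ground_truth=pd.DataFrame(gt),
                   config=config)


def validate_store(path: str | Path) -> list[dict]:
    """Machine-readable diagnostics for a session store.

    Checks group layout, shape consistency across stimuli and against the
    neuropil group, and schedule/trace-length agreement.
    """
    path = Path(path)
    issues: list[dict] = []
    if not path.exists():
        raise IOError(f"store not found: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as err:
        raise IOError(f"unreadable container: {path}") from err
    with f:
        for group in ("raw", "neuropil", "ground_truth"):
            if group not in f:
                issues.append({"path": f"/{group}", "issue": "missing group"})
        if "raw" not in f:
            return issues
        n_rois = None
        n_rep = None
        for name in f["raw"]:
            d = f["raw"][name]
            if d.ndim != 3:
                issues.append({"path": f"/raw/{name}",
                               "issue": f"expected 3-D, got {d.ndim}-D"})
                continue
            if n_rois is None:
                n_rois, n_rep = d.shape[0], d.shape[2]
            if d.shape[0] != n_rois:
                issues.append({"path": f"/raw/{name}",
                               "issue": f"ROI axis {d.shape[0]} != {n_rois}"})
            if d.shape[2] != n_rep:
                issues.append({"path": f"/raw/{name}",
                               "issue": f"repetition axis {d.shape[2]} != {n_rep}"})
            if "neuropil" in f and name not in f["neuropil"]:
                issues.append({"path": f"/neuropil/{name}",
                               "issue": "missing neuropil dataset"})
            elif "neuropil" in f and f["neuropil"][name].shape != d.shape:
                issues.append({"path": f"/neuropil/{name}",
                               "issue": "neuropil shape mismatch"})
            if "schedule" in d.attrs and "frame_rate" in d.attrs:
                sched = json.loads(d.attrs["schedule"])
                fr = float(d.attrs["frame_rate"])
                if "duration" in sched:
                    expected = int(round(sched["duration"] * fr))
                    if abs(d.shape[1] - expected) > 0:
                        issues.append({
                            "path": f"/raw/{name}",
                            "issue": f"timing: {d.shape[1]} samples vs "
                                     f"schedule {expected}",
                        })
    return issues
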