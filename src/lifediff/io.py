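"""File formats: trajectory CSV, model parameter files, JSON reports.

Trajectory tables are plain CSV with one row per localization and the
columns ``track_id, frame, t_s, x_um, y_um, state, censored`` (``state``
may be empty for experimental data).  Coordinates are µm, times s,
frame indices 0-based; frames within a track must be consecutive.

Model parameter files are JSON or YAML mappings with the keys
``n_states, D, lam, lam_b, k, q, eps`` (units fixed to µm and s).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig
from .models import KineticModel
from .simulate import Trajectory, TrajectoryEnsemble

__all__ = ["read_trajectories", "write_trajectories", "read_model",
           "write_model", "write_report", "AnalysisConfig"]

REQUIRED_COLUMNS = ("track_id", "frame", "t_s", "x_um", "y_um")


class TrajectoryFormatError(ValueError):
    """Raised for malformed trajectory tables; carries offending rows."""


def write_trajectories(ensemble: TrajectoryEnsemble, path) -> None:
    ensemble.to_dataframe().to_csv(path, index=False)


def read_trajectories(path, frame_dt: Optional[float] = None,
                      on_gap: str = "error") -> TrajectoryEnsemble:
    """Read a trajectory CSV into an ensemble.

    ``on_gap`` controls tracks with non-consecutive frame numbers:
    ``"error"`` rejects the file, ``"split"`` breaks them into separate
    tracks, ``"drop"`` discards them.  The frame interval is inferred
    from the ``t_s`` column unless given explicitly; it must be uniform.
    """
    if on_gap not in ("error", "split", "drop"):
        raise ValueError("on_gap must be 'error', 'split' or 'drop'")
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TrajectoryFormatError(f"{path}: file is empty") from None
    if df.empty:
        raise TrajectoryFormatError(f"{path}: no trajectory rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {missing}")
    for col in ("frame", "t_s", "x_um", "y_um"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]
            raise TrajectoryFormatError(
                f"{path}: non-numeric values in column {col!r} "
                f"near lines {lines}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df[["frame", "x_um", "y_um"]].isna().any().any():
        raise TrajectoryFormatError(f"{path}: missing coordinate values")

    if frame_dt is None:
        # per-row interval normalized by the frame-number difference, so
        # that frame gaps (handled below) do not break the inference
        grouped = df.groupby("track_id")
        dts = grouped["t_s"].diff() / grouped["frame"].diff()
        dts = dts.dropna()
        if dts.empty:
            raise TrajectoryFormatError(
                f"{path}: cannot infer frame interval from single-frame tracks")
        frame_dt = float(dts.mode().iloc[0])
        if not np.allclose(dts, frame_dt, atol=frame_dt * 1e-3):
            raise TrajectoryFormatError(
                f"{path}: non-uniform frame interval (expected {frame_dt})")

    tracks = []
    next_id = 0
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy(dtype=int)
        breaks = np.where(np.diff(frames) != 1)[0]
        if breaks.size and on_gap == "error":
            raise TrajectoryFormatError(
                f"{path}: track {tid} has non-consecutive frames")
        if breaks.size and on_gap == "drop":
            continue
        pieces = np.split(np.arange(frames.size), breaks + 1)
        for piece in pieces:
            sub = g.iloc[piece]
            xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
            states = None
            if "state" in sub.columns and sub["state"].notna().all():
                states = sub["state"].to_numpy(dtype=int) - 1
            censored = bool(sub["censored"].iloc[-1]) if "censored" in sub else False
            tracks.append(Trajectory(track_id=next_id, frame_dt=frame_dt,
                                     xy=xy, states=states, censored=censored))
            next_id += 1
    if not tracks:
        raise TrajectoryFormatError(f"{path}: no usable tracks")
    return TrajectoryEnsemble(trajectories=tracks, frame_dt=frame_dt)


def read_model(path) -> KineticModel:
    """Read a kinetic model from a JSON or YAML parameter file."""
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text))
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of model parameters")
    if "n_states" in data and len(data["D"]) != data["n_states"]:
        raise ValueError(f"{path}: n_states does not match D")
    return KineticModel.from_dict(data)


def write_model(model: KineticModel, path) -> None:
    path = Path(path)
    data = model.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report, path) -> None:
    """Write an analysis report (or any dict) as stable, versioned JSON."""
    data = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    data = _jsonable(data)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
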