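"""File formats and round-trip helpers.

CSV is the interchange spine (traces, spikes, bouts, metrics), TIFF holds
images and movies, HDF5 is an alternative movie container, and JSON holds
configuration, ground truth and statistics. Trace CSVs carry a ``time_s``
column plus one column per ROI; events/epochs and the frame rate travel in
a ``<name>.meta.json`` sidecar so the round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .datatypes import BoutTable, StainedStack, TraceSet

__all__ = [
    "read_stack",
    "write_stack",
    "read_traces",
    "write_traces",
    "read_movie",
    "write_movie",
    "read_bouts",
    "write_bouts",
    "write_table",
    "write_json",
]

_FLOAT_FMT = "%.17g"  # lossless for float64


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def read_stack(layout: dict[str, str | Path],
               voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
               ) -> StainedStack:
    """Read a multi-channel stack from per-role TIFF files.

    ``layout`` maps channel roles to TIFF paths (each a z-stack, or a
    single plane read as one z). All channels must agree in shape.
    """
    if not layout:
        raise ValueError("layout must declare at least one channel role")
    channels, roles = [], []
    for role, path in layout.items():
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"channel {role!r}: no file {p}")
        arr = np.asarray(tifffile.imread(p), dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        channels.append(arr)
        roles.append(role)
    shapes = {c.shape for c in channels}
    if len(shapes) > 1:
        raise ValueError(f"channel shapes disagree across roles: {sorted(shapes)}")
    return StainedStack(np.stack(channels), tuple(roles), voxel_size)


def write_stack(stack: StainedStack, directory: str | Path,
                prefix: str = "stack") -> dict[str, Path]:
    """Write one TIFF per channel role; returns the layout mapping."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    layout = {}
    for role in stack.channel_roles:
        p = directory / f"{prefix}_{role}.tif"
        tifffile.imwrite(p, stack.channel(role).astype(np.float32))
        layout[role] = p
    return layout


def write_traces(ts: TraceSet, path: str | Path) -> Path:
    """Write a trace set as CSV plus a metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(ts.values, columns=list(ts.roi_labels))
    df.insert(0, "time_s", ts.times)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {"fps": ts.fps, "kind": ts.kind, "events": ts.events,
            "epochs": {k: list(v) for k, v in ts.epochs.items()},
            "meta": {k: v for k, v in ts.meta.items()
                     if isinstance(v, (int, float, str, bool))}}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_traces(path: str | Path) -> TraceSet:
    """Read a trace-set CSV (with optional metadata sidecar).

    Without a sidecar, fps is inferred from the ``time_s`` column and the
    trace kind defaults to ``dff``. Decimal parsing is locale-independent
    (C locale floats, as written).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(
            f"{path}: malformed header; expected 'time_s' plus one column "
            f"per ROI, got {list(df.columns)}"
        )
    labels = [c for c in df.columns if c != "time_s"]
    if not labels:
        raise ValueError(f"{path}: no ROI columns")
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        fps = float(meta["fps"])
        kind = meta.get("kind", "dff")
        events = {k: float(v) for k, v in meta.get("events", {}).items()}
        epochs = {k: tuple(v) for k, v in meta.get("epochs", {}).items()}
    else:
        t = df["time_s"].to_numpy()
        fps = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
        kind, events, epochs = "dff", {}, {}
    return TraceSet(df[labels].to_numpy(), fps=fps, roi_labels=tuple(labels),
                    events=events, epochs=epochs, kind=kind)


def write_movie(movie: np.ndarray, path: str | Path) -> Path:
    """Write a time × y × x movie as TIFF (pages = frames) or HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("movie", data=np.asarray(movie, dtype=np.float32))
    else:
        tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))
    return path


def read_movie(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return np.asarray(f["movie"], dtype=float)
    return np.asarray(tifffile.imread(path), dtype=float)


def write_bouts(bouts: BoutTable, path: str | Path) -> Path:
    """Write a bout table (start, label, fish, group + feature columns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = bouts.to_frame()
    feat = pd.DataFrame(bouts.features,
                        columns=[f"f{i}" for i in range(bouts.features.shape[1])])
    pd.concat([df, feat], axis=1).to_csv(path, index=False,
                                         float_format=_FLOAT_FMT)
    return path


def read_bouts(path: str | Path) -> BoutTable:
    df = pd.read_csv(path)
    needed = {"start_s", "label"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    feats = (df[feat_cols].to_numpy() if feat_cols
             else np.zeros((len(df), 220)))
    return BoutTable(df["start_s"].to_numpy(), feats,
                     df["label"].to_numpy(dtype=object),
                     fish_id=str(df["fish_id"].iloc[0]) if "fish_id" in df and len(df) else "fish0",
                     group=str(df["group"].iloc[0]) if "group" in df and len(df) else "")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        raise TypeError(f"not JSON-serialisable: {type(v)}")

    path.write_text(json.dumps(obj, indent=1, default=default))
    return path
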