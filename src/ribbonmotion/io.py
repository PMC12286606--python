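"""File formats: CSV track/spot tables and TIFF stacks with JSON sidecars.

All public tables are in micrometres and seconds; frame indices are
bookkeeping.  Track tables have columns track_id, frame, t_seconds,
x_um, y_um, z_um[, label].  A mapping profile reads Imaris-style
position exports (Position X/Y/Z, Time, TrackID).  Image stacks are
multi-page TIFF in TZYX (or ZYX) order with a JSON sidecar carrying the
voxel size and frame interval.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import ImageStack
from .linking import SPOT_COLUMNS
from .tracks import TRACK_COLUMNS, TrackSet

IMARIS_COLUMNS = {
    "Position X": "x_um",
    "Position Y": "y_um",
    "Position Z": "z_um",
    "Time": "frame",
    "TrackID": "track_id",
}


def write_track_table(ts: TrackSet, path) -> Path:
    path = Path(path)
    ts.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    return path


def read_track_table(path, profile: str = "native", dt: float | None = None) -> TrackSet:
    """Read a track table; ``profile`` is "native" or "imaris".

    Imaris exports carry Time as a 1-based frame index and no absolute
    time; ``dt`` (seconds) is then required to reconstruct t_seconds.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if profile == "imaris":
        df = _from_imaris(df, dt)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return TrackSet.from_dataframe(df)


def _from_imaris(df: pd.DataFrame, dt: float | None) -> pd.DataFrame:
    missing = [c for c in IMARIS_COLUMNS if c not in df.columns]
    if missing:
        native = [IMARIS_COLUMNS[c] for c in missing]
        raise ValueError(f"Imaris table missing columns {missing} (needed for {native})")
    out = df.rename(columns=IMARIS_COLUMNS)[list(IMARIS_COLUMNS.values())].copy()
    out["frame"] = out["frame"].astype(int) - 1  # Imaris Time is 1-based
    if dt is None:
        raise ValueError("dt (seconds per frame) required for the imaris profile")
    out["t_seconds"] = out["frame"] * float(dt)
    return out


def read_spot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_spot_table(spots: pd.DataFrame, path) -> Path:
    path = Path(path)
    spots.to_csv(path, index=False, float_format="%.17g")
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    meta = {
        "voxel_size_um": list(stack.voxel_size),
        "dt_seconds": stack.dt,
        "axes": "TZYX" if stack.is_movie else "ZYX",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path) -> ImageStack:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    return ImageStack(
        data=np.asarray(data, dtype=float),
        voxel_size=tuple(meta["voxel_size_um"]),
        dt=meta.get("dt_seconds"),
    )
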