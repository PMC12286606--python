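"""Track containers shared by the simulation, linking and analysis stages.

A :class:`Track` is an ordered sequence of 3D positions with integer frame
indices and absolute times.  Coordinates are always micrometres and times
seconds; frame indices are internal bookkeeping only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["track_id", "frame", "t_seconds", "x_um", "y_um", "z_um"]


@dataclass
class Track:
    """One trajectory: strictly increasing frames, >=2 points.

    Attributes
    ----------
    track_id : int
    frames : (N,) int array, strictly increasing
    t : (N,) float array, seconds
    xyz : (N, 3) float array, micrometres
    label : optional ground-truth motion class or direction label
    spot_ids : optional source detection ids (one per point)
    """

    track_id: int
    frames: np.ndarray
    t: np.ndarray
    xyz: np.ndarray
    label: str | None = None
    spot_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        n = len(self.frames)
        if n < 2:
            raise ValueError("a track needs at least 2 points")
        if self.xyz.shape != (n, 3):
            raise ValueError(f"xyz must be ({n}, 3), got {self.xyz.shape}")
        if self.t.shape != (n,):
            raise ValueError("t must match frames in length")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def start(self) -> np.ndarray:
        return self.xyz[0]

    @property
    def end(self) -> np.ndarray:
        return self.xyz[-1]

    @property
    def net_displacement(self) -> np.ndarray:
        return self.xyz[-1] - self.xyz[0]

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def frame_interval(self) -> float:
        """Sampling interval in seconds, inferred from time vs frame index.

        Raises if the track is not uniformly sampled up to closed gaps
        (i.e. t must equal t0 + frame * dt).
        """
        df = np.diff(self.frames)
        dt_all = np.diff(self.t) / df
        dt = float(np.median(dt_all))
        if dt <= 0 or not np.allclose(dt_all, dt, rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform sampling interval")
        return dt


@dataclass
class TrackSet:
    """An ordered collection of tracks, convertible to/from a flat table."""

    tracks: list[Track] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    @property
    def track_ids(self) -> list[int]:
        return [tr.track_id for tr in self.tracks]

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten to one row per point (columns ``TRACK_COLUMNS`` + label)."""
        rows = []
        for tr in self.tracks:
            df = pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "frame": tr.frames,
                    "t_seconds": tr.t,
                    "x_um": tr.xyz[:, 0],
                    "y_um": tr.xyz[:, 1],
                    "z_um": tr.xyz[:, 2],
                }
            )
            df["label"] = tr.label if tr.label is not None else ""
            rows.append(df)
        if not rows:
            return pd.DataFrame(columns=TRACK_COLUMNS + ["label"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrackSet":
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        tracks = []
        for tid, grp in df.groupby("track_id", sort=True):
            grp = grp.sort_values("frame")
            label = None
            if "label" in grp.columns:
                lab = grp["label"].iloc[0]
                if isinstance(lab, str) and lab:
                    label = lab
            tracks.append(
                Track(
                    track_id=int(tid),
                    frames=grp["frame"].to_numpy(),
                    t=grp["t_seconds"].to_numpy(),
                    xyz=grp[["x_um", "y_um", "z_um"]].to_numpy(),
                    label=label,
                )
            )
        return cls(tracks)
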