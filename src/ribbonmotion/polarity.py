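"""Track angles relative to the apical-basal axis and the base fraction.

EB3 comets mark growing microtubule plus ends; the direction of their
tracks relative to each cell's apex->base axis measures network
polarity.  The convention: a track moving straight to the base makes a
0 deg angle, straight to the apex 180 deg, and a track is base-directed
iff its angle is strictly below 90 deg.  The analysis is 2D (xy), using
only each track's start and end positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CellGeometry
from .tracks import Track, TrackSet

logger = logging.getLogger(__name__)


def fold_angle_deg(delta: float) -> float:
    """Fold an angle difference into [0, 180] via min(d, 360 - d)."""
    d = abs(delta) % 360.0
    return min(d, 360.0 - d)


@dataclass
class TrackAngle:
    track_id: int
    angle_deg: float
    base_directed: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg <= 180.0:
            raise ValueError("angle_deg must be in [0, 180]")
        if self.base_directed != (self.angle_deg < 90.0):
            raise ValueError("base_directed must equal (angle_deg < 90)")


def track_angle(track: Track, geometry: CellGeometry) -> TrackAngle:
    """Angle of a track's net xy displacement against the base axis.

    Raises on a zero net xy displacement (undefined direction); use
    :func:`track_angles` to skip such tracks with a logged reason.
    """
    dxy = track.net_displacement[:2]
    if np.allclose(dxy, 0.0):
        raise ValueError(f"track {track.track_id}: zero net xy displacement")
    theta = math.degrees(math.atan2(dxy[1], dxy[0]))
    a = fold_angle_deg(theta - geometry.axis_angle_deg)
    return TrackAngle(track_id=track.track_id, angle_deg=a, base_directed=a < 90.0)


def track_angles(ts: TrackSet, geometry: CellGeometry) -> list[TrackAngle]:
    """Angles for every track with a nonzero net xy displacement."""
    out = []
    for tr in ts:
        try:
            out.append(track_angle(tr, geometry))
        except ValueError as e:
            logger.info("excluded from angle analysis: %s", e)
    return out


def angles_dataframe(angles: list[TrackAngle], cell_id: str | int | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        [{"track_id": a.track_id, "angle_deg": a.angle_deg, "base_directed": a.base_directed}
         for a in angles]
    )
    if cell_id is not None:
        df["cell_id"] = cell_id
    return df


def base_fraction(angles: list[TrackAngle]) -> dict:
    """Base-directed fraction and counts (< 90 deg, strict).

    ``percent_int`` rounds to an integer and ``apical_percent_1dp`` to
    one decimal, matching how such fractions are conventionally quoted.
    """
    if not angles:
        raise ValueError("empty angle list")
    n = len(angles)
    n_base = sum(a.base_directed for a in angles)
    frac = n_base / n
    return {
        "fraction": frac,
        "n_base": n_base,
        "n_total": n,
        "percent_int": int(round(100.0 * frac)),
        "apical_percent_1dp": round(100.0 * (1.0 - frac), 1),
    }
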