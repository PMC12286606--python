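"""Hair-cell geometry: the apical-basal axis and the nucleus plane.

Hair cells are polarized: the mechanosensory hair bundle sits at the apex
and the presynaptic active zone at the base.  All polarity and
apical/basal classifications are made relative to the apex->base axis.
The angle convention follows the field's: a displacement toward the base
makes a 0 deg track angle, toward the apex 180 deg.

The nucleus plane is a scalar coordinate along the apex->base axis (in
micrometres from the apex projection) separating "above nucleus"
(apical; ribbon precursors) from "below nucleus" (basal; maturing
ribbons).  The papers' workflows locate it by visual inspection; here it
is an explicit input, known exactly for synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as3(p) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 2:
        p = np.append(p, 0.0)
    if p.size != 3:
        raise ValueError("points must be 2D or 3D")
    return p


@dataclass
class CellGeometry:
    """Apex/base axis of one hair cell plus the nucleus plane.

    Parameters
    ----------
    apex_point, base_point : 2D or 3D positions (um); 2D points get z=0.
    nucleus_plane : scalar coordinate along the apex->base axis (um from
        the apex), strictly between the apex (0) and base projections.
    """

    apex_point: np.ndarray
    base_point: np.ndarray
    nucleus_plane: float
    axis_angle_deg: float = field(init=False)

    def __post_init__(self) -> None:
        self.apex_point = _as3(self.apex_point)
        self.base_point = _as3(self.base_point)
        v = self.base_point - self.apex_point
        if np.allclose(v, 0):
            raise ValueError("apex_point and base_point must differ")
        self.nucleus_plane = float(self.nucleus_plane)
        if not (0.0 < self.nucleus_plane < float(np.linalg.norm(v))):
            raise ValueError("nucleus_plane must lie strictly between apex and base")
        if np.allclose(v[:2], 0):
            raise ValueError("axis is degenerate in the xy plane")
        self.axis_angle_deg = float(np.degrees(np.arctan2(v[1], v[0])) % 360.0)

    @property
    def axis_vector(self) -> np.ndarray:
        """Unit vector pointing from apex to base (3D)."""
        v = self.base_point - self.apex_point
        return v / np.linalg.norm(v)

    @property
    def axis_length_um(self) -> float:
        return float(np.linalg.norm(self.base_point - self.apex_point))

    @property
    def axis_xy(self) -> np.ndarray:
        """Unit vector of the base direction in the xy plane."""
        a = np.radians(self.axis_angle_deg)
        return np.array([np.cos(a), np.sin(a)])

    def axial_coordinate(self, point) -> float:
        """Project a point onto the apex->base axis (um from the apex)."""
        return float(np.dot(_as3(point) - self.apex_point, self.axis_vector))

    def is_basal(self, point) -> bool:
        """True when the point projects beyond the nucleus plane."""
        return self.axial_coordinate(point) > self.nucleus_plane
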