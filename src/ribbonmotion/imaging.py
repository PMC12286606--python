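"""Image-side procedures of the workflow.

Covers translational drift registration, Laplacian-of-Gaussian spot
detection with subvoxel refinement, 3D puncta segmentation and counting
(threshold -> optional watershed split -> connected components -> size
filter), apical/basal compartment assignment, 2D area quantification of
max-projected stacks, and kinocilium-height developmental staging.

Conventions: 3D arrays are (z, y, x); 4D arrays are (t, z, y, x); voxel
size is (dx, dy, dz) in micrometres; all positions returned to the user
are (x, y, z) in micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label
from skimage.registration import phase_cross_correlation
from skimage.restoration import rolling_ball
from skimage.segmentation import watershed

from .geometry import CellGeometry

# Developmental stage bins by kinocilium height (um): the kinocilium is
# the tallest part of the hair bundle and its height tracks maturation.
STAGE_BINS = (
    ("early", 0.0, 1.5),        # [0, 1.5)
    ("intermediate", 1.5, 10.0),  # [1.5, 10)
    ("late", 10.0, 18.0),       # [10, 18]
    ("mature", 18.0, np.inf),   # (18, inf)
)
DEFAULT_Z_INTERVAL_UM = 0.425


@dataclass
class ImageStack:
    """Intensity array plus physical metadata.

    data : (z, y, x) for a single volume or (t, z, y, x) for a timelapse
    voxel_size : (dx, dy, dz) um
    dt : frame interval in seconds (timelapses only)
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    dt: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be 3D (z,y,x) or 4D (t,z,y,x)")
        if any(d < 1 for d in self.data.shape):
            raise ValueError("all dimensions must be >= 1")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive values")
        self.voxel_size = vs
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def is_movie(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] if self.is_movie else 1

    def frame(self, i: int) -> np.ndarray:
        return self.data[i] if self.is_movie else self.data

    def voxels_zyx(self) -> np.ndarray:
        """Voxel size reordered to match array axes (dz, dy, dx)."""
        dx, dy, dz = self.voxel_size
        return np.array([dz, dy, dx])


@dataclass
class PunctaRecord:
    """One segmented 3D (or projected 2D) object."""

    centroid_um: tuple[float, float, float]  # (x, y, z)
    volume_voxels: int
    volume_um3: float
    area_um2: float | None = None
    compartment: str = "unassigned"  # apical | basal | unassigned


@dataclass
class StageLabel:
    stage: str
    kinocilium_height_um: float


# ---------------------------------------------------------------------------
# drift registration
# ---------------------------------------------------------------------------

def correct_drift(series: ImageStack, upsample_factor: int = 10):
    """Register every frame to the first by translation.

    Offsets are estimated by phase cross-correlation (subvoxel via
    ``upsample_factor``) and applied with spline interpolation.  Returns
    the registered stack and the per-frame offsets in voxels, (t, 3)
    array ordered (dz, dy, dx): `frame + shift(offset)` aligns to frame 0.
    """
    if not series.is_movie or series.n_frames < 2:
        raise ValueError("drift correction needs a movie with >= 2 frames")
    ref = series.frame(0).astype(float)
    if not np.any(ref):
        raise ValueError("reference frame is empty; nothing to register")
    offsets = np.zeros((series.n_frames, 3))
    out = np.empty_like(series.data, dtype=float)
    out[0] = ref
    for i in range(1, series.n_frames):
        mov = series.frame(i).astype(float)
        if not np.any(mov):
            raise ValueError(f"frame {i} is empty; nothing to register")
        shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=upsample_factor)
        offsets[i] = shift
        out[i] = ndi.shift(mov, shift, order=1, mode="constant", cval=0.0)
    out = np.clip(out, 0.0, None)
    return ImageStack(out, series.voxel_size, series.dt), offsets


# ---------------------------------------------------------------------------
# spot detection
# ---------------------------------------------------------------------------

def detect_spots(
    volume: ImageStack,
    expected_diameter_um: float,
    quality_threshold: float = 0.0,
) -> pd.DataFrame:
    """Detect diffraction-limited spots in one volume.

    Band-pass by a scale-normalized Laplacian of Gaussian tuned to the
    expected diameter, local maxima with minimum separation equal to the
    diameter, then intensity-weighted subvoxel centroid refinement.
    Quality is the scale-normalized LoG response at the peak (intensity
    units); it is not comparable across software packages.

    Returns a DataFrame with columns x_um, y_um, z_um, quality.
    """
    if expected_diameter_um <= 0:
        raise ValueError("expected_diameter_um must be positive")
    vz = volume.voxels_zyx()
    if expected_diameter_um < min(volume.voxel_size[:2]):
        raise ValueError("expected diameter is smaller than one voxel")
    img = volume.frame(0).astype(float) if not volume.is_movie else None
    if img is None:
        raise ValueError("detect_spots expects a single 3D volume")

    # LoG scale: for a Gaussian blob, response peaks when sigma ~ r/sqrt(3) in 3D
    sigma_um = expected_diameter_um / (2.0 * np.sqrt(3.0))
    sigma_vox = sigma_um / vz
    response = -ndi.gaussian_laplace(img, sigma=sigma_vox) * sigma_um**2
    # calibrate so the quality of an ideal matched Gaussian spot equals
    # its amplitude (intensity units)
    response = response / _log_unit_response(sigma_um, vz)

    # minimum separation = expected diameter, anisotropic footprint
    radii = np.maximum(1, np.round(expected_diameter_um / vz).astype(int))
    footprint = np.ones(2 * radii + 1, dtype=bool)
    peaks = peak_local_max(
        response,
        footprint=footprint,
        threshold_abs=max(quality_threshold, 1e-12),
        exclude_border=False,
    )
    rows = []
    for pz, py, px in peaks:
        q = float(response[pz, py, px])
        if q < quality_threshold:
            continue
        c = _subvoxel_centroid(img, (pz, py, px))
        dx, dy, dz = volume.voxel_size
        rows.append({"x_um": c[2] * dx, "y_um": c[1] * dy, "z_um": c[0] * dz, "quality": q})
    return pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "quality"])


def _log_unit_response(sigma_um: float, voxels_zyx: np.ndarray) -> float:
    """Peak LoG response of a unit-amplitude Gaussian spot of sd sigma_um."""
    half = np.maximum(1, np.ceil(4 * sigma_um / voxels_zyx).astype(int))
    grids = np.meshgrid(*[np.arange(-h, h + 1) * v for h, v in zip(half, voxels_zyx)], indexing="ij")
    r2 = sum(g**2 for g in grids)
    blob = np.exp(-r2 / (2 * sigma_um**2))
    resp = -ndi.gaussian_laplace(blob, sigma=sigma_um / voxels_zyx) * sigma_um**2
    return float(resp.max())


def _subvoxel_centroid(img: np.ndarray, peak: tuple[int, int, int]) -> np.ndarray:
    """Intensity-weighted centroid within a 3x3x3 neighborhood (voxels)."""
    lo = [max(0, p - 1) for p in peak]
    hi = [min(s, p + 2) for p, s in zip(peak, img.shape)]
    sub = img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    w = sub - sub.min()
    if w.sum() <= 0:
        return np.array(peak, dtype=float)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    return np.array([float((g * w).sum() / w.sum()) for g in grids])


def detect_spots_movie(
    movie: ImageStack, expected_diameter_um: float, quality_threshold: float = 0.0
) -> pd.DataFrame:
    """Run detect_spots per frame; returns a spot table with frame and time."""
    if not movie.is_movie:
        raise ValueError("expected a 4D movie")
    if movie.dt is None:
        raise ValueError("movie lacks a frame interval (dt)")
    frames = []
    for f in range(movie.n_frames):
        vol = ImageStack(movie.data[f], movie.voxel_size)
        det = detect_spots(vol, expected_diameter_um, quality_threshold)
        det.insert(0, "frame", f)
        det.insert(1, "t_seconds", f * movie.dt)
        frames.append(det)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "spot_id", np.arange(len(out)))
    return out


# ---------------------------------------------------------------------------
# 3D puncta segmentation / counting
# ---------------------------------------------------------------------------

def segment_puncta_3d(
    volume: ImageStack,
    intensity_threshold: float,
    split_touching: bool = True,
    min_size_vox: int = 0,
    max_size_vox: int = 183_500,
    min_seed_separation_um: float | None = None,
) -> list[PunctaRecord]:
    """Threshold, optionally watershed-split, and count 3D objects.

    The binary mask (intensity >= threshold) is split at distance-
    transform maxima when ``split_touching``, labelled with
    26-connectivity, and size-filtered to [min_size_vox, max_size_vox]
    inclusive.  Centroids are intensity-weighted, reported in um (x,y,z).
    """
    if min_size_vox > max_size_vox:
        raise ValueError("min_size_vox > max_size_vox")
    img = volume.frame(0).astype(float)
    mask = img >= intensity_threshold
    if not mask.any():
        return []
    if split_touching:
        labels = _watershed_split(mask, volume, min_seed_separation_um)
    else:
        labels = sk_label(mask, connectivity=3)  # 26-connectivity in 3D
    dx, dy, dz = volume.voxel_size
    voxel_um3 = dx * dy * dz
    records = []
    for lab in range(1, labels.max() + 1):
        sel = labels == lab
        n = int(sel.sum())
        if n < max(min_size_vox, 1) or n > max_size_vox:
            continue
        com = ndi.center_of_mass(img * sel)
        records.append(
            PunctaRecord(
                centroid_um=(com[2] * dx, com[1] * dy, com[0] * dz),
                volume_voxels=n,
                volume_um3=n * voxel_um3,
            )
        )
    return records


def _watershed_split(
    mask: np.ndarray, volume: ImageStack, min_seed_separation_um: float | None
) -> np.ndarray:
    """Distance-transform watershed; seeds = EDT maxima."""
    vz = volume.voxels_zyx()
    dist = ndi.distance_transform_edt(mask, sampling=vz)
    sep = min_seed_separation_um if min_seed_separation_um is not None else 2 * float(vz.max())
    radii = np.maximum(1, np.round(sep / vz).astype(int))
    footprint = np.ones(2 * radii + 1, dtype=bool)
    seeds = peak_local_max(dist, footprint=footprint, labels=mask, exclude_border=False)
    seeds = _dedupe_seeds(seeds, dist, vz, sep)
    markers = np.zeros(mask.shape, dtype=int)
    for i, s in enumerate(seeds, start=1):
        markers[tuple(s)] = i
    if markers.max() == 0:
        return sk_label(mask, connectivity=3)
    return watershed(-dist, markers, mask=mask)


def _dedupe_seeds(seeds: np.ndarray, dist: np.ndarray, voxels_zyx: np.ndarray, sep_um: float):
    """Keep one seed per cluster closer than sep_um (plateau ties)."""
    if len(seeds) == 0:
        return seeds
    order = np.argsort([-dist[tuple(s)] for s in seeds])
    kept: list[np.ndarray] = []
    for i in order:
        p = seeds[i] * voxels_zyx
        if all(np.linalg.norm(p - q) >= sep_um for q in kept):
            kept.append(p)
    return np.array([np.round(p / voxels_zyx).astype(int) for p in kept])


def classify_apical_basal(
    puncta: list[PunctaRecord], geometry: CellGeometry
) -> tuple[list[PunctaRecord], dict[str, int]]:
    """Assign each punctum to the apical or basal compartment.

    Centroids projecting beyond the nucleus plane along the apex->base
    axis are basal; the rest apical.  Returns the labelled records and
    the per-compartment counts.
    """
    if geometry is None:
        raise ValueError("geometry required for compartment assignment")
    counts = {"apical": 0, "basal": 0}
    out = []
    for p in puncta:
        comp = "basal" if geometry.is_basal(p.centroid_um) else "apical"
        counts[comp] += 1
        out.append(
            PunctaRecord(p.centroid_um, p.volume_voxels, p.volume_um3, p.area_um2, comp)
        )
    return out, counts


# ---------------------------------------------------------------------------
# 2D area quantification
# ---------------------------------------------------------------------------

def quantify_areas_2d(
    volume: ImageStack,
    rolling_ball_radius_px: int = 50,
    threshold: float = 0.0,
    min_area_um2: float = 0.002,
    split_touching: bool = True,
) -> list[float]:
    """Puncta areas from a max projection, in um^2.

    Max-project along z, rolling-ball background subtraction, threshold,
    optional 2D watershed split, 8-connected components, and a strict
    minimum-area filter (areas < min_area_um2 dropped).
    """
    if rolling_ball_radius_px < 1:
        raise ValueError("rolling_ball_radius_px must be >= 1")
    img = volume.frame(0).astype(float)
    proj = img.max(axis=0)
    bg = rolling_ball(proj, radius=rolling_ball_radius_px)
    corr = proj - bg
    if threshold > corr.max():
        warnings.warn("threshold above maximum intensity; no objects", stacklevel=2)
        return []
    mask = corr >= threshold
    if split_touching:
        dist = ndi.distance_transform_edt(mask)
        seeds = peak_local_max(dist, min_distance=2, labels=mask, exclude_border=False)
        seeds = _dedupe_seeds(seeds, dist, np.ones(2), 3.0)
        markers = np.zeros(mask.shape, dtype=int)
        for i, s in enumerate(seeds, start=1):
            markers[tuple(s)] = i
        labels = watershed(-dist, markers, mask=mask) if markers.max() else sk_label(mask, connectivity=2)
    else:
        labels = sk_label(mask, connectivity=2)
    dx, dy, _ = volume.voxel_size
    px_area = dx * dy
    areas = []
    for lab in range(1, labels.max() + 1):
        a = float((labels == lab).sum()) * px_area
        if a >= min_area_um2:
            areas.append(a)
    return areas


# ---------------------------------------------------------------------------
# developmental staging
# ---------------------------------------------------------------------------

def stage_cell(n_z_slices: int, z_interval_um: float = DEFAULT_Z_INTERVAL_UM) -> StageLabel:
    """Stage a hair cell from the number of z-slices spanning its kinocilium.

    height = n_z_slices * z_interval_um; bins: early [0, 1.5),
    intermediate [1.5, 10), late [10, 18], mature (18, inf).
    """
    if n_z_slices < 0:
        raise ValueError("n_z_slices must be non-negative")
    height = n_z_slices * z_interval_um
    return StageLabel(stage=stage_from_height(height), kinocilium_height_um=height)


def stage_from_height(height_um: float) -> str:
    if height_um < 0:
        raise ValueError("height must be non-negative")
    if height_um < 1.5:
        return "early"
    if height_um < 10.0:
        return "intermediate"
    if height_um <= 18.0:
        return "late"
    return "mature"
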