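"""Ground-truth synthetic data: tracks, comet fields, fusion pairs, images.

The generator emulates the statistical structure of ribbon-precursor and
EB3-comet imaging in developing zebrafish lateral-line hair cells:

* 3D trajectories from three motion classes — confined (reflected
  Brownian motion in a spherical corral), Brownian (free diffusion), and
  directed (constant velocity plus residual diffusion) — sampled at
  frame intervals of 3–100 s with i.i.d. Gaussian localization noise;
* microtubule plus-end (EB3) comet fields in a polarized cell geometry
  with a configurable base-directed fraction;
* converging track pairs that merge (fusion scenarios);
* rendered image stacks of anisotropic Gaussian spots over background
  with Poisson or Gaussian noise, at hair-cell imaging voxel sizes
  (0.04 x 0.04 x 0.17 um by default).

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .fusion import FusionEvent
from .geometry import CellGeometry
from .imaging import ImageStack, PunctaRecord
from .tracks import Track, TrackSet

MOTION_MODELS = ("confined", "brownian", "directed")

# default per-axis localization noise: half the xy voxel (um)
DEFAULT_SIGMA_LOC = 0.02


@dataclass
class MotionParams:
    """Parameters of one simulated motion class.

    D in um^2/s; v in um/s (directed only); R_conf in um (confined
    only); sigma_loc per-axis localization s.d. in um; dt frame interval
    in seconds.
    """

    model: str
    D: float = 0.0
    v: float = 0.0
    direction: np.ndarray | None = None
    R_conf: float | None = None
    sigma_loc: float = DEFAULT_SIGMA_LOC
    dt: float = 5.0
    n_frames: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MOTION_MODELS:
            raise ValueError(f"unknown motion model {self.model!r}; use one of {MOTION_MODELS}")
        if self.D < 0 or self.v < 0 or self.sigma_loc < 0:
            raise ValueError("D, v and sigma_loc must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.model == "confined":
            if self.R_conf is None or self.R_conf <= 0:
                raise ValueError("confined model needs R_conf > 0")
        if self.model == "directed":
            if self.direction is None:
                raise ValueError("directed model needs a direction")
            d = np.asarray(self.direction, dtype=float)
            n = np.linalg.norm(d)
            if n == 0:
                raise ValueError("direction must be nonzero")
            self.direction = d / n


@dataclass
class LabeledTrackSet:
    """Tracks plus per-track ground-truth labels and parameters."""

    tracks: TrackSet
    labels: dict[int, str] = field(default_factory=dict)
    params: dict[int, MotionParams] = field(default_factory=dict)
    geometry: CellGeometry | None = None

    def __post_init__(self) -> None:
        ids = set(self.tracks.track_ids)
        if set(self.labels) != ids:
            raise ValueError("labels must correspond one-to-one with track ids")

    def __len__(self) -> int:
        return len(self.tracks)


@dataclass
class RenderParams:
    """Rendering model for synthetic fluorescence stacks.

    voxel_size (dx, dy, dz) um; psf_sigma (sigma_xy, sigma_z) um;
    noise_model one of {"poisson", "gaussian", "none"} (gaussian uses
    ``gaussian_sd``).
    """

    voxel_size: tuple[float, float, float] = (0.04, 0.04, 0.17)
    psf_sigma: tuple[float, float] = (0.1, 0.25)
    spot_amplitude: float = 200.0
    background: float = 10.0
    noise_model: str = "poisson"
    gaussian_sd: float = 2.0
    stack_shape: tuple[int, int, int] = (64, 64, 16)  # (nx, ny, nz)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size) or any(s <= 0 for s in self.psf_sigma):
            raise ValueError("voxel sizes and PSF sigmas must be positive")
        if self.spot_amplitude <= 0 or self.background < 0:
            raise ValueError("spot_amplitude must be positive, background >= 0")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError("noise_model must be poisson, gaussian or none")
        if any(n < 1 for n in self.stack_shape):
            raise ValueError("stack_shape entries must be >= 1")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the stack (x, y, z) in um."""
        nx, ny, nz = self.stack_shape
        dx, dy, dz = self.voxel_size
        return (nx * dx, ny * dy, nz * dz)


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def simulate_track(
    params: MotionParams,
    start=(0.0, 0.0, 0.0),
    track_id: int = 0,
    rng: np.random.Generator | None = None,
) -> Track:
    """Simulate one 3D trajectory sampled at k*dt, k = 0..n_frames-1.

    brownian: i.i.d. per-axis Gaussian increments with variance 2*D*dt.
    directed: the same plus a deterministic v*dt*direction per frame.
    confined: Brownian steps reflected at the sphere of radius R_conf
    about the start (mirror fold of the radial overshoot, sub-stepped so
    single steps stay small relative to the corral).  Localization noise
    is added independently per frame and axis at the end.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    start = np.asarray(start, dtype=float)
    n, dt = params.n_frames, params.dt

    if params.model == "confined":
        xyz = _confined_path(params, start, rng)
    else:
        steps = rng.normal(0.0, math.sqrt(2.0 * params.D * dt), size=(n - 1, 3))
        if params.model == "directed":
            steps = steps + params.v * dt * params.direction
        xyz = start + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])

    if params.sigma_loc > 0:
        xyz = xyz + rng.normal(0.0, params.sigma_loc, size=xyz.shape)

    frames = np.arange(n)
    return Track(track_id=track_id, frames=frames, t=frames * dt, xyz=xyz,
                 label=params.model)


def _confined_path(params: MotionParams, start: np.ndarray, rng) -> np.ndarray:
    """Reflected Brownian motion inside a sphere of radius R_conf about start.

    Sub-steps keep 2*D*dt_sub <= (R/4)^2 so a single proposal rarely
    overshoots by more than the corral radius (avoids tunneling).
    """
    R = float(params.R_conf)
    n, dt, D = params.n_frames, params.dt, params.D
    if D == 0:
        return np.tile(start, (n, 1))
    n_sub = max(1, math.ceil(2.0 * D * dt / (R / 4.0) ** 2))
    sd = math.sqrt(2.0 * D * dt / n_sub)
    pos = np.zeros(3)
    out = np.empty((n, 3))
    out[0] = 0.0
    for k in range(1, n):
        for step in rng.normal(0.0, sd, size=(n_sub, 3)):
            pos = _reflect_step(pos, pos + step, R)
        out[k] = pos
    return start + out


def _reflect_step(p0: np.ndarray, p1: np.ndarray, R: float) -> np.ndarray:
    """Mirror the overshooting part of p0->p1 at the sphere |x| = R.

    The segment is reflected across the tangent plane at its exit
    point, repeatedly if the reflected remainder exits again.
    """
    for _ in range(64):
        if np.dot(p1, p1) <= R * R:
            return p1
        d = p1 - p0
        a = float(np.dot(d, d))
        b = 2.0 * float(np.dot(p0, d))
        c = float(np.dot(p0, p0)) - R * R
        disc = max(b * b - 4.0 * a * c, 0.0)
        t = (-b + math.sqrt(disc)) / (2.0 * a)
        q = p0 + t * d
        nrm = q / R
        rem = p1 - q
        p1 = q + rem - 2.0 * float(np.dot(rem, nrm)) * nrm
        p0 = q
    # pathological step: clamp to the boundary
    return p1 / np.linalg.norm(p1) * R


def simulate_trackset(
    mixture: list[tuple[MotionParams, int]],
    geometry: CellGeometry | None = None,
    seed: int = 0,
    start_box_um: float = 10.0,
) -> LabeledTrackSet:
    """Simulate a labeled mixture of motion classes.

    Each (params, count) entry contributes ``count`` tracks; starts are
    drawn uniformly from a cube of side ``start_box_um`` (or between
    apex and base when a geometry is given).  Deterministic under seed.
    """
    if not mixture:
        raise ValueError("mixture must not be empty")
    if any(cnt < 0 for _, cnt in mixture):
        raise ValueError("counts must be >= 0")
    ss = np.random.SeedSequence(seed)
    total = sum(cnt for _, cnt in mixture)
    children = ss.spawn(total + 1)
    start_rng = np.random.default_rng(children[0])
    tracks, labels, pdict = [], {}, {}
    tid = 0
    for params, cnt in mixture:
        for _ in range(cnt):
            if geometry is not None:
                u = start_rng.uniform(0.15, 0.85)
                jitter = start_rng.uniform(-0.5, 0.5, size=3)
                start = geometry.apex_point + u * (geometry.base_point - geometry.apex_point) + jitter
            else:
                start = start_rng.uniform(0.0, start_box_um, size=3)
            rng = np.random.default_rng(children[1 + tid])
            tr = simulate_track(params, start=start, track_id=tid, rng=rng)
            tracks.append(tr)
            labels[tid] = params.model
            pdict[tid] = params
            tid += 1
    return LabeledTrackSet(TrackSet(tracks), labels, pdict, geometry)


def simulate_comet_field(
    geometry: CellGeometry,
    n: int,
    p_base: float = 0.8,
    v: float = 0.1,
    lifetime_frames: int = 6,
    dt: float = 7.0,
    seed: int = 0,
    jitter_deg: float = 15.0,
    D: float = 0.0,
    sigma_loc: float = 0.0,
) -> LabeledTrackSet:
    """Simulate EB3-like plus-end comets in a polarized cell.

    Each comet is a directed track of ``lifetime_frames`` points moving
    along the apex->base axis (probability ``p_base``) or the reverse,
    with wrapped-Gaussian angular jitter about the axis in the xy plane.
    Labels record the true direction ("base" or "apex").
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= p_base <= 1.0:
        raise ValueError("p_base must be in [0, 1]")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)
    master = np.random.default_rng(children[0])
    to_base = master.random(n) < p_base
    axis_angle = math.radians(geometry.axis_angle_deg)
    tracks, labels = [], {}
    for i in range(n):
        rng = np.random.default_rng(children[1 + i])
        theta = axis_angle + (0.0 if to_base[i] else math.pi)
        theta += math.radians(jitter_deg) * rng.standard_normal()
        direction = np.array([math.cos(theta), math.sin(theta), 0.0])
        u = rng.uniform(0.15, 0.85)
        start = geometry.apex_point + u * (geometry.base_point - geometry.apex_point)
        start = start + np.append(rng.uniform(-0.5, 0.5, size=2), 0.0)
        params = MotionParams(
            model="directed", D=D, v=v, direction=direction,
            sigma_loc=sigma_loc, dt=dt, n_frames=lifetime_frames,
        )
        tracks.append(simulate_track(params, start=start, track_id=i, rng=rng))
        labels[i] = "base" if to_base[i] else "apex"
    return LabeledTrackSet(TrackSet(tracks), labels, {}, geometry)


def simulate_fusion_pair(
    meet_point=(5.0, 5.0, 1.0),
    meet_frame: int = 10,
    post_frames: int = 8,
    dt: float = 50.0,
    approach_speed: float = 0.01,
    sigma_loc: float = 0.0,
    seed: int = 0,
    track_ids: tuple[int, int] = (0, 1),
):
    """Two tracks converging to a merge, plus the ground-truth event.

    The pair approaches ``meet_point`` from opposite sides at
    ``approach_speed`` (um/s), coincides exactly at ``meet_frame`` and —
    when ``post_frames`` > 0 — stays coincident (up to independent
    localization noise) for ``post_frames`` more frames.  With
    ``post_frames`` = 0 the tracks instead pass through and separate
    again (a crossing, not a fusion) and no ground-truth event is
    returned.
    """
    if meet_frame < 2:
        raise ValueError("meet_frame must be >= 2")
    if post_frames < 0:
        raise ValueError("post_frames must be >= 0")
    rng = np.random.default_rng(seed)
    meet = np.asarray(meet_point, dtype=float)
    step = approach_speed * dt
    direction = np.array([1.0, 0.0, 0.0])

    n_post = post_frames if post_frames > 0 else meet_frame
    n = meet_frame + 1 + n_post
    frames = np.arange(n)
    k = (meet_frame - frames).astype(float)  # frames until the meeting

    if post_frames > 0:
        ka = np.maximum(k, 0.0)
        a = meet - np.outer(ka, step * direction)
        b = meet + np.outer(ka, step * direction)
        truth = FusionEvent(
            track_id_a=track_ids[0], track_id_b=track_ids[1],
            merge_frame=meet_frame, merge_time_s=meet_frame * dt,
            co_persistence_s=post_frames * dt, reaches_end=True,
        )
    else:
        a = meet - np.outer(k, step * direction)   # passes through
        b = meet + np.outer(k, step * direction)
        truth = None

    if sigma_loc > 0:
        a = a + rng.normal(0.0, sigma_loc, size=a.shape)
        b = b + rng.normal(0.0, sigma_loc, size=b.shape)
    tr_a = Track(track_ids[0], frames, frames * dt, a)
    tr_b = Track(track_ids[1], frames, frames * dt, b)
    return tr_a, tr_b, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_stack(
    positions_um,
    rp: RenderParams,
    seed: int = 0,
    dt: float | None = None,
) -> ImageStack:
    """Render spots as anisotropic Gaussians over background, noise last.

    ``positions_um`` is either an (n, 3) array of (x, y, z) positions
    (static volume) or a list of such arrays, one per frame (movie).
    Positions must lie inside the stack bounds.
    """
    rng = np.random.default_rng(seed)
    if isinstance(positions_um, (list, tuple)) and (
        len(positions_um) == 0 or np.asarray(positions_um[0]).ndim == 2
    ):
        frames = [_render_volume(np.asarray(p, dtype=float), rp) for p in positions_um]
        data = np.stack(frames)
    else:
        pos = np.asarray(positions_um, dtype=float).reshape(-1, 3)
        data = _render_volume(pos, rp)
    data = _apply_noise(data, rp, rng)
    return ImageStack(data, rp.voxel_size, dt)


def render_movie_from_tracks(ts: TrackSet, rp: RenderParams, seed: int = 0) -> ImageStack:
    """Render a 4D movie of a track set (frames 0..max frame)."""
    if len(ts) == 0:
        raise ValueError("empty track set")
    dts = {tr.frame_interval() for tr in ts}
    if len(dts) != 1:
        raise ValueError("tracks must share one frame interval")
    dt = dts.pop()
    n_frames = max(int(tr.frames.max()) for tr in ts) + 1
    per_frame = [[] for _ in range(n_frames)]
    for tr in ts:
        for f, p in zip(tr.frames, tr.xyz):
            per_frame[int(f)].append(p)
    frames = [np.asarray(p, dtype=float).reshape(-1, 3) for p in per_frame]
    return render_stack(frames, rp, seed=seed, dt=dt)


def _render_volume(pos: np.ndarray, rp: RenderParams) -> np.ndarray:
    nx, ny, nz = rp.stack_shape
    dx, dy, dz = rp.voxel_size
    sxy, sz = rp.psf_sigma
    img = np.full((nz, ny, nx), float(rp.background))
    ext = rp.extent_um
    for x, y, z in pos:
        if not (0 <= x < ext[0] and 0 <= y < ext[1] and 0 <= z < ext[2]):
            raise ValueError(f"position ({x}, {y}, {z}) um outside stack bounds {ext}")
        # local window of +-4 sigma around the spot, in voxels
        cx, cy, cz = x / dx, y / dy, z / dz
        rx, ry, rz = int(4 * sxy / dx) + 1, int(4 * sxy / dy) + 1, int(4 * sz / dz) + 1
        x0, x1 = max(0, int(cx) - rx), min(nx, int(cx) + rx + 1)
        y0, y1 = max(0, int(cy) - ry), min(ny, int(cy) + ry + 1)
        z0, z1 = max(0, int(cz) - rz), min(nz, int(cz) + rz + 1)
        gx = np.arange(x0, x1) * dx - x
        gy = np.arange(y0, y1) * dy - y
        gz = np.arange(z0, z1) * dz - z
        g = (
            np.exp(-gz[:, None, None] ** 2 / (2 * sz**2))
            * np.exp(-gy[None, :, None] ** 2 / (2 * sxy**2))
            * np.exp(-gx[None, None, :] ** 2 / (2 * sxy**2))
        )
        img[z0:z1, y0:y1, x0:x1] += rp.spot_amplitude * g
    return img


def _apply_noise(data: np.ndarray, rp: RenderParams, rng) -> np.ndarray:
    if rp.noise_model == "poisson":
        return rng.poisson(data).astype(float)
    if rp.noise_model == "gaussian":
        return np.clip(data + rng.normal(0.0, rp.gaussian_sd, size=data.shape), 0.0, None)
    return data


def make_puncta_scene(
    geometry: CellGeometry,
    n_apical: int,
    n_basal: int,
    rp: RenderParams,
    seed: int = 0,
    min_separation_um: float = 1.0,
    margin_um: float = 0.3,
) -> tuple[ImageStack, list[PunctaRecord]]:
    """Render a volume with known apical/basal puncta counts.

    Apical centroids project strictly above the nucleus plane (by
    ``margin_um``), basal strictly below.  Returns the image and the
    ground-truth records.  Raises when the scene cannot host the
    requested spots at the minimum pairwise separation.
    """
    if n_apical < 0 or n_basal < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    ext = rp.extent_um
    placed: list[np.ndarray] = []
    truth: list[PunctaRecord] = []

    def _try_place(compartment: str) -> np.ndarray:
        for _ in range(2000):
            p = rng.uniform([0.5, 0.5, 0.5], np.asarray(ext) - 0.5)
            axial = geometry.axial_coordinate(p)
            if compartment == "apical" and not (axial < geometry.nucleus_plane - margin_um):
                continue
            if compartment == "basal" and not (axial > geometry.nucleus_plane + margin_um):
                continue
            if all(np.linalg.norm(p - q) >= min_separation_um for q in placed):
                return p
        raise ValueError("scene too small to place spots at the minimum separation")

    for comp, count in (("apical", n_apical), ("basal", n_basal)):
        for _ in range(count):
            p = _try_place(comp)
            placed.append(p)
            truth.append(
                PunctaRecord(centroid_um=tuple(p), volume_voxels=1, volume_um3=0.0,
                             compartment=comp)
            )
    stack = render_stack(np.asarray(placed).reshape(-1, 3), rp, seed=seed + 1)
    return stack, truth
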