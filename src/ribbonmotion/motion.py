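"""MSD analysis and motion classification of ribbon-precursor tracks.

For each track the time-averaged mean squared displacement

    MSD(k*dt) = < | r(t + k*dt) - r(t) |^2 >_t          (3D)

is computed over all valid start times, and the anomalous-diffusion
exponent alpha is the slope of an ordinary least-squares fit of
log MSD against log tau over the first 25% of lags.  alpha > 1
indicates directional motion with velocity, alpha = 1 Brownian motion,
and alpha < 1 confined motion or subdiffusion.  Classification is
binary — directional (alpha > 1) vs confined (alpha <= 1) — so the two
reported fractions always partition the track set.  A second, simpler
criterion flags "long" tracks whose start-to-end displacement exceeds
1 um, and long tracks are further broken down by direction relative to
the cell axis and by position relative to the nucleus plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CellGeometry
from .polarity import fold_angle_deg
from .tracks import Track, TrackSet

MIN_POINTS_MSD = 10
LONG_TRACK_UM = 1.0
DEFAULT_FIT_FRACTION = 0.25
DEFAULT_ANGLE_BAND = (60.0, 120.0)


class DegenerateTrackError(ValueError):
    """Raised when every fitted lag has zero MSD (stationary track)."""


@dataclass
class MSDProfile:
    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    track_id: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd_um2 < 0):
            raise ValueError("MSD must be non-negative")


@dataclass
class MotionFit:
    alpha: float
    log_prefactor: float
    r_squared: float
    n_lags_fit: int
    track_id: int


def compute_msd(track: Track) -> MSDProfile:
    """Time-averaged MSD of one track over all valid displacement pairs.

    The track must have >= 10 points and uniform sampling up to closed
    gaps.  A pair (f, f + k) contributes to lag k*dt only when both
    endpoint frames exist; nothing is interpolated across gaps.
    """
    if track.n_points < MIN_POINTS_MSD:
        raise ValueError(f"MSD needs >= {MIN_POINTS_MSD} points, got {track.n_points}")
    dt = track.frame_interval()
    f0 = track.frames - track.frames[0]
    span = int(f0[-1])
    gapless = span == track.n_points - 1
    lags, msds, counts = [], [], []
    if gapless:
        for k in range(1, span + 1):
            d = track.xyz[k:] - track.xyz[:-k]
            sq = (d * d).sum(axis=1)
            lags.append(k * dt)
            msds.append(float(sq.mean()))
            counts.append(len(sq))
    else:
        index = {int(f): i for i, f in enumerate(f0)}
        for k in range(1, span + 1):
            sq = [
                float(((track.xyz[index[f + k]] - track.xyz[i]) ** 2).sum())
                for f, i in index.items()
                if f + k in index
            ]
            if not sq:
                continue
            lags.append(k * dt)
            msds.append(float(np.mean(sq)))
            counts.append(len(sq))
    return MSDProfile(
        lags_s=np.asarray(lags), msd_um2=np.asarray(msds),
        n_pairs=np.asarray(counts, dtype=int), track_id=track.track_id,
    )


def fit_alpha(profile: MSDProfile, fit_fraction: float = DEFAULT_FIT_FRACTION) -> MotionFit:
    """Power-law exponent from a log-log OLS fit of the first lags.

    The fit window is the first max(2, ceil(fit_fraction * K)) lags of
    the K available; zero-MSD lags are excluded.  Raises
    :class:`DegenerateTrackError` when fewer than two usable lags
    remain (e.g. a stationary track).
    """
    K = len(profile.lags_s)
    n_fit = max(2, math.ceil(fit_fraction * K))
    lags = profile.lags_s[:n_fit]
    msd = profile.msd_um2[:n_fit]
    ok = msd > 0
    if ok.sum() < 2:
        raise DegenerateTrackError(
            f"track {profile.track_id}: fewer than 2 nonzero lags in the fit window"
        )
    x = np.log(lags[ok])
    y = np.log(msd[ok])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MotionFit(
        alpha=float(slope), log_prefactor=float(intercept), r_squared=r2,
        n_lags_fit=int(ok.sum()), track_id=profile.track_id,
    )


def classify_motion(fit: MotionFit, alpha_threshold: float = 1.0) -> str:
    """Binary motion class: alpha > threshold directional, else confined.

    alpha exactly at the threshold counts as confined so that the two
    reported bins partition all tracks.
    """
    return "directional" if fit.alpha > alpha_threshold else "confined"


def track_displacement(track: Track) -> tuple[float, bool]:
    """Start-to-end 3D distance and the strict >1 um long-track flag."""
    d = float(np.linalg.norm(track.net_displacement))
    return d, d > LONG_TRACK_UM


def assign_direction_and_position(
    track: Track,
    geometry: CellGeometry,
    angle_band: tuple[float, float] = DEFAULT_ANGLE_BAND,
) -> tuple[str, str]:
    """Direction (base/apex/undetermined) and position of a long track.

    The angle of the net xy displacement against the base axis decides
    direction: below the band "base", above it "apex", inside it (or a
    zero net displacement) "undetermined".  Position compares the
    track's mean axial coordinate with the nucleus plane.
    """
    lo, hi = angle_band
    dxy = track.net_displacement[:2]
    if np.allclose(dxy, 0.0):
        direction = "undetermined"
    else:
        theta = math.degrees(math.atan2(dxy[1], dxy[0]))
        a = fold_angle_deg(theta - geometry.axis_angle_deg)
        direction = "base" if a < lo else ("apex" if a > hi else "undetermined")
    mean_axial = float(np.mean([geometry.axial_coordinate(p) for p in track.xyz]))
    position = "below_nucleus" if mean_axial > geometry.nucleus_plane else "above_nucleus"
    return direction, position


def classify_tracks(
    ts: TrackSet,
    geometry: CellGeometry | None = None,
    fit_fraction: float = DEFAULT_FIT_FRACTION,
    angle_band: tuple[float, float] = DEFAULT_ANGLE_BAND,
) -> pd.DataFrame:
    """Per-track analysis table (one row per track).

    Columns: track_id, n_spots, alpha, r_squared, displacement_um,
    motion_class, long_track, direction, position, excluded_reason.
    Tracks that cannot be fit (too short or degenerate) get a reason
    and NaN alpha; direction/position need a geometry and a long track.
    """
    rows = []
    for tr in ts:
        row = {
            "track_id": tr.track_id,
            "n_spots": tr.n_points,
            "alpha": np.nan,
            "r_squared": np.nan,
            "motion_class": "",
            "excluded_reason": "",
        }
        disp, long_track = track_displacement(tr)
        row["displacement_um"] = disp
        row["long_track"] = long_track
        try:
            fit = fit_alpha(compute_msd(tr), fit_fraction)
            row["alpha"] = fit.alpha
            row["r_squared"] = fit.r_squared
            row["motion_class"] = classify_motion(fit)
        except DegenerateTrackError:
            row["excluded_reason"] = "degenerate (stationary) MSD"
        except ValueError as e:
            row["excluded_reason"] = str(e)
        direction, position = "", ""
        if geometry is not None and long_track:
            direction, position = assign_direction_and_position(tr, geometry, angle_band)
        row["direction"] = direction
        row["position"] = position
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_motion(classified: pd.DataFrame) -> dict:
    """Summary fractions of a per-track classification table.

    Returns the directional fraction (of tracks with a valid alpha),
    the long-track fraction, direction and position breakdowns of long
    tracks, and the per-class alpha lists for distribution comparisons.
    """
    if len(classified) == 0:
        raise ValueError("empty track set")
    fit = classified[classified["motion_class"] != ""]
    out: dict = {
        "n_tracks": int(len(classified)),
        "n_fit": int(len(fit)),
        "directional_fraction": float("nan"),
        "confined_fraction": float("nan"),
        "long_track_fraction": float((classified["long_track"]).mean()),
        "alpha_by_class": {},
        "direction_breakdown": {},
        "position_breakdown": {},
    }
    if len(fit) > 0:
        frac = float((fit["motion_class"] == "directional").mean())
        out["directional_fraction"] = frac
        out["confined_fraction"] = 1.0 - frac
        out["alpha_by_class"] = {
            cls: grp["alpha"].tolist() for cls, grp in fit.groupby("motion_class")
        }
    long_tracks = classified[classified["long_track"] & (classified["direction"] != "")]
    if len(long_tracks) > 0:
        out["direction_breakdown"] = (
            long_tracks["direction"].value_counts(normalize=True).to_dict()
        )
        out["position_breakdown"] = (
            long_tracks["position"].value_counts(normalize=True).to_dict()
        )
    return out


def ensemble_msd(ts: TrackSet) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble mean MSD over tracks: pair-count-weighted average per lag."""
    sums: dict[float, float] = {}
    counts: dict[float, int] = {}
    for tr in ts:
        prof = compute_msd(tr)
        for lag, m, n in zip(prof.lags_s, prof.msd_um2, prof.n_pairs):
            lag = float(lag)
            sums[lag] = sums.get(lag, 0.0) + m * n
            counts[lag] = counts.get(lag, 0) + int(n)
    lags = np.array(sorted(sums))
    means = np.array([sums[l] / counts[l] for l in lags])
    return lags, means
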