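"""Shared fixtures and scene builders for the test suite.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ribbonmotion as rm
from ribbonmotion.linking import LinkerParams, filter_tracks, link_tracks


@pytest.fixture
def geometry() -> rm.CellGeometry:
    """A horizontal cell: apex at x=2, base at x=12, nucleus halfway."""
    return rm.CellGeometry((2.0, 2.0, 1.0), (12.0, 2.0, 1.0), 5.0)


def straight_track(track_id=0, start=(0.0, 0.0, 0.0), step=(1.0, 0.0, 0.0), n=10, dt=5.0):
    """Noiseless track with a constant per-frame step."""
    start = np.asarray(start, dtype=float)
    step = np.asarray(step, dtype=float)
    frames = np.arange(n)
    xyz = start + np.outer(frames, step)
    return rm.Track(track_id, frames, frames * dt, xyz)


def spot_table_from_tracks(tracks) -> pd.DataFrame:
    rows = []
    sid = 0
    for tr in tracks:
        for f, t, p in zip(tr.frames, tr.t, tr.xyz):
            rows.append(
                dict(spot_id=sid, frame=int(f), t_seconds=float(t),
                     x_um=p[0], y_um=p[1], z_um=p[2])
            )
            sid += 1
    return pd.DataFrame(rows).sort_values(["frame", "spot_id"]).reset_index(drop=True)


def mixed_motion_scene(seed=42, n_directed=6, n_confined=14, n_frames=30, dt=5.0):
    """Collision-free labeled mixture of directed and confined tracks.

    Directed tracks (v=0.05 um/s, D=0.002 um^2/s) run along +x in their
    own y band; confined tracks (R=0.25 um, D=0.01 um^2/s) sit in a
    separate column with inter-track spacing above the ribbon linking
    gate, so linking is unambiguous on the rendered movie.
    """
    dirp = rm.MotionParams(model="directed", v=0.05, D=0.002, direction=(1, 0, 0),
                           sigma_loc=0.0, dt=dt, n_frames=n_frames)
    confp = rm.MotionParams(model="confined", D=0.01, R_conf=0.25,
                            sigma_loc=0.0, dt=dt, n_frames=n_frames)
    ss = np.random.SeedSequence(seed).spawn(n_directed + n_confined)
    tracks, labels = [], {}
    tid = 0
    for i in range(n_directed):
        tr = rm.simulate_track(dirp, start=(2.0, 2.5 + 3.0 * i, 2.2),
                               track_id=tid, rng=np.random.default_rng(ss[tid]))
        tracks.append(tr)
        labels[tid] = "directed"
        tid += 1
    for i in range(n_confined):
        tr = rm.simulate_track(
            confp, start=(12.5, 2.0 + 1.4 * i, 1.2 if i % 2 else 3.2),
            track_id=tid, rng=np.random.default_rng(ss[tid]))
        tracks.append(tr)
        labels[tid] = "confined"
        tid += 1
    return rm.LabeledTrackSet(rm.TrackSet(tracks), labels)


def mixed_scene_render_params():
    return rm.RenderParams(
        voxel_size=(0.1, 0.1, 0.2), psf_sigma=(0.15, 0.3),
        stack_shape=(145, 220, 22), noise_model="poisson",
        spot_amplitude=300.0, background=10.0,
    )


def run_end_to_end(scene, rp, seed=7):
    """Render -> detect -> link -> filter -> MSD classification."""
    movie = rm.render_movie_from_tracks(scene.tracks, rp, seed=seed)
    spots = rm.detect_spots_movie(movie, 0.5, quality_threshold=60.0)
    linked = link_tracks(spots, LinkerParams(max_link_dist_um=1.13, max_gap_frames=1))
    kept = filter_tracks(linked, min_spots=10)
    table = rm.classify_tracks(kept)
    return movie, spots, linked, kept, table
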