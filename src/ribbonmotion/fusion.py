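"""Fusion-event detection between tracked ribbon precursors.

Ribbons behave like biomolecular condensates: two precursors can merge
into one larger object.  Operationally, a fusion is scored once the two
objects can no longer be resolved separately (inter-centroid distance
below a resolution limit) and stay together for at least five minutes
or for the remainder of the timelapse.  Divisions (fissions, the
time-reversed pattern) are reported separately and never subtracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .tracks import Track, TrackSet

DEFAULT_D_RES_UM = 0.3     # ~ ribbon detection diameter (0.427 um) minus margin
DEFAULT_T_MIN_S = 300.0    # "at least 5 min"


@dataclass
class FusionParams:
    """Operational definition of a merge.

    d_res_um: distance below which two objects are unresolved.
    t_min_s: minimum co-persistence unless the merge reaches the end of
    the timelapse.  dt: frame interval (seconds).
    """

    d_res_um: float = DEFAULT_D_RES_UM
    t_min_s: float = DEFAULT_T_MIN_S
    dt: float | None = None

    def __post_init__(self) -> None:
        if self.d_res_um <= 0:
            raise ValueError("d_res_um must be positive")
        if self.t_min_s < 0:
            raise ValueError("t_min_s must be >= 0")


@dataclass
class FusionEvent:
    track_id_a: int
    track_id_b: int
    merge_frame: int
    merge_time_s: float
    co_persistence_s: float
    reaches_end: bool


def detect_fusions(
    ts: TrackSet, params: FusionParams, timelapse_end_s: float | None = None
) -> list[FusionEvent]:
    """Detect merge events between all co-existing track pairs.

    A candidate merge at frame f requires the inter-object distance to
    be below ``d_res_um`` at f and at every later frame where both
    tracks exist.  The merged state must persist for at least
    ``t_min_s`` or to the end of the timelapse; one partner may
    terminate at the merge with the survivor carrying the merged object
    on, so persistence is counted to the later of the two track ends.
    Each unordered pair yields at most one event.
    """
    if params.dt is None:
        raise ValueError("FusionParams.dt is required to apply the persistence rule")
    if timelapse_end_s is None:
        timelapse_end_s = max((float(tr.t[-1]) for tr in ts), default=0.0)
    events: list[FusionEvent] = []
    for tr_a, tr_b in combinations(ts, 2):
        ev = _pair_event(tr_a, tr_b, params, timelapse_end_s)
        if ev is not None:
            events.append(ev)
    return events


def _pair_event(
    tr_a: Track, tr_b: Track, params: FusionParams, timelapse_end_s: float
) -> FusionEvent | None:
    common, ia, ib = np.intersect1d(tr_a.frames, tr_b.frames, return_indices=True)
    if len(common) == 0:
        return None
    d = np.linalg.norm(tr_a.xyz[ia] - tr_b.xyz[ib], axis=1)
    close = d < params.d_res_um
    if not close.any():
        return None
    # earliest frame from which the pair is unresolved at every later
    # co-existing frame (suffix of all-close frames)
    suffix_ok = np.flip(np.logical_and.accumulate(np.flip(close)))
    idx = int(np.argmax(suffix_ok))
    if not suffix_ok[idx]:
        return None
    merge_frame = int(common[idx])
    merge_time = float(tr_a.t[ia[idx]])
    end_time = max(float(tr_a.t[-1]), float(tr_b.t[-1]))
    co_persistence = end_time - merge_time
    reaches_end = end_time >= timelapse_end_s - params.dt / 2.0
    if co_persistence + 1e-9 >= params.t_min_s or reaches_end:
        return FusionEvent(
            track_id_a=tr_a.track_id, track_id_b=tr_b.track_id,
            merge_frame=merge_frame, merge_time_s=merge_time,
            co_persistence_s=co_persistence, reaches_end=reaches_end,
        )
    return None


def detect_fissions(
    ts: TrackSet, params: FusionParams, timelapse_start_s: float = 0.0
) -> list[FusionEvent]:
    """Divisions scored by the time-reversed fusion rule (reported only)."""
    if len(ts) == 0:
        return []
    f_max = max(int(tr.frames.max()) for tr in ts)
    t_max = max(float(tr.t.max()) for tr in ts)
    rev = TrackSet(
        [
            Track(
                tr.track_id,
                frames=(f_max - tr.frames)[::-1],
                t=(t_max - tr.t)[::-1],
                xyz=tr.xyz[::-1],
            )
            for tr in ts
        ]
    )
    return detect_fusions(rev, params)


def min_persistence_frames(params: FusionParams) -> int:
    """The 5-min criterion in frames: ceil(t_min_s / dt)."""
    if params.dt is None:
        raise ValueError("dt required")
    return math.ceil(params.t_min_s / params.dt)


def fusion_rate(events_per_sample: list[int] | list[list[FusionEvent]], n_samples: int | None = None):
    """Mean and max fusion events per sample (e.g. per neuromast).

    Accepts either per-sample event counts or per-sample event lists.
    When ``n_samples`` exceeds the list length the missing samples count
    zero events.
    """
    counts = [len(e) if isinstance(e, list) else int(e) for e in events_per_sample]
    if n_samples is None:
        n_samples = len(counts)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if len(counts) < n_samples:
        counts = counts + [0] * (n_samples - len(counts))
    mean = sum(counts) / n_samples
    return {"mean_per_sample": mean, "max_per_sample": max(counts), "n_samples": n_samples}
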