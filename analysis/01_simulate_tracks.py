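#!/usr/bin/env python
"""Generate the labeled synthetic track sets used by the downstream analyses.

Simulates the three motion classes seen in ribbon-precursor timelapses
— confined (corralled), Brownian, and directed — at the imaging
conditions of the slower timelapse protocol (dt = 5 s here, within the
3–100 s range used in practice) and writes one CSV per class plus a
mixed labeled set to results/tracks/.
"""

from pathlib import Path

import ribbonmotion as rm
from ribbonmotion.io import write_track_table

OUT = Path("results/tracks")
SEED = 20240901

PARAMS = {
    "brownian": rm.MotionParams(model="brownian", D=0.01, sigma_loc=0.02,
                                dt=5.0, n_frames=100),
    "directed": rm.MotionParams(model="directed", v=0.05, D=0.002,
                                direction=(1, 0, 0), sigma_loc=0.02,
                                dt=5.0, n_frames=100),
    "confined": rm.MotionParams(model="confined", D=0.01, R_conf=0.25,
                                sigma_loc=0.02, dt=5.0, n_frames=100),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, (name, params) in enumerate(PARAMS.items()):
        lts = rm.simulate_trackset([(params, 500)], seed=SEED + i)
        path = write_track_table(lts.tracks, OUT / f"{name}.csv")
        print(f"{name}: 500 tracks x {params.n_frames} frames -> {path}")
    mixture = [(PARAMS["directed"], 150), (PARAMS["confined"], 350)]
    lts = rm.simulate_trackset(mixture, seed=SEED + 10)
    path = write_track_table(lts.tracks, OUT / "mixture_30pct_directed.csv")
    print(f"mixture (30% directed / 70% confined): 500 tracks -> {path}")


if __name__ == "__main__":
    main()
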