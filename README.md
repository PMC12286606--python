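# ribbonmotion

Trajectory and image analysis of presynaptic **ribbon-precursor transport in
developing zebrafish lateral-line hair cells**, built for researchers who
quantify organelle motion and synapse assembly from 4D fluorescence
timelapses.

Hair cells are polarized: the mechanosensory hair bundle sits at the apex,
the presynaptic active zone at the base. During development, small
Ribeye-rich ribbon precursors travel along a microtubule network whose plus
ends (marked by EB3 comets) grow toward the base, and precursors can fuse
into larger ribbons. This package reimplements the full quantitative
workflow around those observations as a tested, reusable library:

- **Motion classification by MSD exponent.** For each track the
  time-averaged mean squared displacement
  `MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩` is fit as a power law `MSD(τ) ∝ τ^α`
  (ordinary least squares in log–log space over the first 25 % of lags).
  `α > 1` indicates directional motion with velocity, `α = 1` Brownian
  motion, `α < 1` confined motion or subdiffusion.
- **Displacement classification.** Tracks with a start-to-end displacement
  `> 1 µm` are flagged as directed ("long"), and long tracks are broken
  down by direction relative to the cell axis and by position relative to
  the nucleus plane.
- **Track linking.** Frame-to-frame linking with constant-velocity
  prediction, globally optimal gated assignment, and gap closing
  (defaults: 1.13 µm / 1-frame gap for ribbons; 1.0 µm / 3-frame gap for
  EB3 comets; track-length filters of ≥5, >5, and ≥10 spots for the
  ribbon, comet, and MSD stages respectively).
- **Polarity analysis.** Track angles relative to each cell's apex→base
  axis (base = 0°, apex = 180°, computed in 2D from start/end positions);
  a track is base-directed iff its angle is strictly below 90°.
- **Fusion scoring.** Two objects merge once their distance falls below a
  resolution limit (default 0.3 µm) and they stay together for ≥5 min or
  for the remainder of the timelapse; rates are summarized per sample
  (neuromast).
- **3D puncta counting and staging.** Threshold → watershed →
  26-connected components → size filter (max 183,500 voxels),
  apical/basal classification against the nucleus plane, 2D area
  quantification (min 0.002 µm²), and developmental staging from
  kinocilium height (0.425 µm z-steps; early <1.5 µm, intermediate
  1.5–10 µm, late 10–18 µm, mature >18 µm).
- **Synthetic data with ground truth.** Simulators for the three motion
  classes (confined = reflected Brownian motion in a sphere, Brownian,
  directed), polarized comet fields, converging fusion pairs, and rendered
  image stacks (anisotropic Gaussian PSF over background, Poisson noise,
  0.04 × 0.04 × 0.17 µm voxels by default), so every stage is testable
  without any imaging data.

## Worked example

```python
import numpy as np
import ribbonmotion as rm

# simulate 500 free-diffusion tracks at ribbon-imaging conditions
p = rm.MotionParams(model="brownian", D=0.01, sigma_loc=0.0, dt=5.0, n_frames=100)
lts = rm.simulate_trackset([(p, 500)], seed=1)
alphas = [rm.fit_alpha(rm.compute_msd(tr)).alpha for tr in lts.tracks]
print(round(float(np.median(alphas)), 4))   # 0.9915  -> Brownian: alpha ~ 1

# polarity arithmetic on counted comet tracks (2069 of 2598 below 90 deg)
from ribbonmotion.polarity import TrackAngle
angles = [TrackAngle(i, 45.0, True) for i in range(2069)] + \
         [TrackAngle(2069 + i, 135.0, False) for i in range(529)]
res = rm.base_fraction(angles)
print(res["percent_int"], res["apical_percent_1dp"])   # 80 20.4
```

The median fitted exponent of the simulated Brownian set is 0.9915 —
within the expected `α ≈ 1` for free diffusion — and the counted comet
field rounds to 80 % base-directed growth with a 20.4 % apical complement.

## Analysis scripts

The `analysis/` directory holds numbered, narrative drivers that exercise
the library end to end and write their tables under `results/`:

1. `01_simulate_tracks.py` — labeled track sets for the three motion classes
2. `02_msd_classification.py` — per-track α, motion classes, summary fractions
3. `03_comet_polarity.py` — comet-field angles and the base-directed fraction
4. `04_fusion_events.py` — planted-merge detection and per-sample rates
5. `05_puncta_counting.py` — rendered-scene counting, apical/basal split, staging

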