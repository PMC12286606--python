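# Methods

This note documents the models, parameters, and numerical choices behind
`ribbonmotion`, in the spirit of the model documentation shipped with
simulation and statistics packages. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Motion models and the MSD exponent

Per-track motion is classified through the time-averaged mean squared
displacement. For a track sampled at uniform interval Δt,

    MSD(kΔt) = mean over i of |r(t_i + kΔt) − r(t_i)|²   (3D),

computed over every displacement pair whose two endpoint frames exist.
Tracks produced by gap-closing may miss interior frames; a pair is used
whenever both of its endpoints exist — interior missing frames do not
invalidate a pair, and nothing is ever interpolated. Tracks with fewer
than 10 points are excluded from MSD analysis (the same eligibility rule
the rest of the pipeline applies).

The anomalous-diffusion exponent α is the slope of an ordinary
least-squares fit of log MSD against log τ over the first
`max(2, ceil(0.25·K))` of the K available lags. The first-quarter window
is the conventional choice for time-averaged MSD: long lags average few
pairs and are dominated by noise. Log–log OLS (unweighted) gives the
closed-form limits the tests assert: α = 2 exactly on a noiseless
ballistic track (MSD = v²τ²) and α = 1 exactly on an exactly linear
profile (MSD = 6Dτ). Zero-MSD lags are excluded from the fit; a track
whose whole fit window is zero (stationary) raises a "degenerate" error
and is excluded from classification with a logged reason.

Classification is binary: α > 1 → directional, α ≤ 1 → confined. The tie
at exactly 1 goes to "confined" so the two reported bins always partition
the track set; the threshold is exposed in `classify_motion`.

Displacement classification is independent of the MSD: the start-to-end
3D distance, with a strict > 1 µm criterion for "long" (directed) tracks.
Long tracks are assigned a direction from the angle of their net xy
displacement against the base axis — below 60° "base", above 120° "apex",
otherwise "undetermined". The band replaces a manual per-track direction
call and is configurable; because it is a declared approximation of a
visual judgement, no published direction split is treated as a target for
it. Position (above/below nucleus) uses the track's mean axial coordinate
against the nucleus plane.

## Synthetic trajectories

The generator draws from the three motion classes the analysis assumes:

- **Brownian**: i.i.d. per-axis Gaussian increments of variance 2·D·Δt.
- **Directed**: the same plus a deterministic v·Δt·direction per frame
  (constant velocity with residual diffusion).
- **Confined**: reflected Brownian motion inside a sphere of radius
  `R_conf` about the start. The corral model is chosen for testability:
  its stationary distribution is uniform in the ball, giving the
  closed-form long-lag plateau `E|X − Y|² = 6R²/5` that an independent
  Monte-Carlo oracle (two uniform points in the ball) verifies to 10 %.
  Reflection mirrors the overshooting segment across the tangent plane at
  its exit point (repeatedly if needed); proposals are sub-stepped so that
  `2·D·dt_sub ≤ (R/4)²`, which keeps single steps small relative to the
  corral and avoids tunneling artifacts. A naive radial fold was measured
  (during development, via the plateau oracle) to bias the stationary
  density inward by ~10 %, which motivated the exact tangent-plane mirror.

Localization noise is i.i.d. Gaussian per axis per frame; the default
σ_loc = 0.02 µm is half the xy voxel of the imaging protocol. Defaults
Δt = 5 s and 100 frames sit inside the 3–100 s frame-interval range of
the timelapse protocols being emulated.

Comet fields place directed tracks along ± the apex→base axis with
probability `p_base` of the base direction (default 0.8) and
wrapped-Gaussian angular jitter (default s.d. 15°) about the axis — the
jitter models the observed angular spread, for which no published
distribution exists. Fusion scenarios build two tracks that approach a
meeting point symmetrically, coincide exactly at the merge frame, and
either stay coincident (ground-truth fusion) or pass through and separate
(crossing, the constructed negative).

Every simulator is bit-reproducible under a fixed seed; mixtures spawn
independent child seeds per track from one `SeedSequence`.

## Rendering

Spots are rendered as anisotropic Gaussians (σ_xy, σ_z) of fixed
amplitude over a constant background, noise applied last. The default
noise model is Poisson on signal + background (photon-limited detection);
Gaussian and noise-free variants exist for constructed tests. Default
voxels are 0.04 × 0.04 × 0.17 µm, matching the Airyscan acquisition
conventions of the emulated workflow. The renderer refuses positions
outside the stack.

## Image operations

- **Drift registration**: per-frame translation against the first frame
  by phase cross-correlation (subvoxel via upsampling), applied with
  linear interpolation. All-zero frames are rejected (nothing to
  register).
- **Spot detection**: scale-normalized Laplacian-of-Gaussian band-pass at
  σ = diameter/(2√3) per axis (in voxels, so anisotropy is respected),
  local maxima with minimum separation equal to the expected diameter,
  then intensity-weighted subvoxel centroids in a 3×3×3 neighborhood.
  The "quality" is the LoG response normalized so an ideal matched
  Gaussian spot scores its amplitude; it is an in-package scale and not
  transferable to thresholds quoted for proprietary trackers.
- **3D counting**: binary threshold (≥), optional distance-transform
  watershed (seeds = EDT maxima, deduplicated at a minimum physical
  separation to suppress plateau ties), 26-connected components, and an
  inclusive size filter; the default maximum of 183,500 voxels matches
  the counting macro being emulated. Centroids are intensity-weighted.
- **2D areas**: max projection along z, rolling-ball background
  subtraction (default radius 50 px, the plugin's common default),
  threshold, optional watershed split, 8-connected components, and a
  strict minimum-area filter (default 0.002 µm²).
- **Staging**: kinocilium height = number of z-slices × 0.425 µm, binned
  early [0, 1.5), intermediate [1.5, 10), late [10, 18], mature (18, ∞).
  The bin edges follow the published staging convention; the function is
  total over non-negative heights.

Intensity thresholds (97 and 28 in the two live-counting modalities) are
instrument-specific arbitrary units and are config defaults per modality
profile, not constants.

## Linking

Per frame, each active track predicts its next position by
constant-velocity extrapolation (`prediction_weight` w = 1 approximates
autoregressive-motion tracking; w = 0 is nearest-neighbor). A globally
optimal one-to-one assignment between predictions and detections is
solved on squared distances with links beyond the gate forbidden; the
augmented-matrix construction prices an unmatched track or detection at
the gate cost, so any allowed link is preferred to leaving both ends
unmatched, and no birth/death cost model beyond the hard gate is imposed.
During a gap the prediction coasts along the last velocity; tracks
unmatched for more than `max_gap_frames` close. A brute-force
assignment-enumeration oracle in the test suite checks the per-frame
optimum on small scenes. Singleton detections never become tracks.

The assay defaults preserve the printed parameters exactly: ribbons
1.13 µm gate / 1-frame gap with ≥5-spot tracks kept; comets 1.0 µm /
3-frame gap with >5-spot tracks kept; the MSD stage additionally requires
≥10 spots. The "automatic" displacement threshold of the original
tracker is undocumented; the package offers an Otsu split of the
displacement distribution as a declared stand-in, resolved from the
input set at call time (idempotence is guaranteed for resolved numeric
thresholds).

## Polarity

Angles use only each track's start and end xy positions: the track angle
is the absolute difference between the displacement angle and the cell's
axis angle, folded into [0°, 180°]. Base-directed is strictly < 90°, to
match counting conventions in which the 90° boundary is excluded from the
base bin. Zero-xy-displacement tracks are excluded with a logged reason
rather than assigned 90°, since their direction is undefined. Per-cell
axis angles and nucleus planes are explicit inputs — known exactly for
synthetic geometry, user-supplied for real data (the original workflow
measured them interactively).

## Fusion

A merge at frame f requires inter-centroid distance < `d_res_um`
(default 0.3 µm, about the ribbon detection diameter minus a margin;
configurable because the original scoring was visual) at f and at every
later co-existing frame, persisting for ≥ `t_min_s` (default 300 s) or to
the end of the timelapse. One partner may terminate at the merge with the
survivor carrying the merged object, so persistence is counted to the
later of the two track ends. Each unordered pair yields at most one
event. The 5-min criterion in frames is `ceil(t_min_s/dt)` — at the
slowest protocol (Δt = 100 s) that is 3 frames. Fissions are detected by
the time-reversed rule and reported separately, never subtracted.

## Pipeline and configuration

All public tables are in µm and seconds; frame indices are internal. The
runner executes detect → link → filter → MSD/polarity/fusion → summarize,
fail-fast with the failing stage named and partial outputs retained, and
is deterministic under a fixed config and seed. Attrition accounting is
exact at every stage (input = retained + removed). Group comparison is
descriptive only (per-group mean ± SEM and differences); hypothesis
testing is deliberately out of scope.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis assumes:
motion-class MSD behavior, polarized comet directions, convergent merges,
and Gaussian-spot images with Poisson noise. It does not model
photophysics (bleaching, blinking), filament networks or
microtubule-switching events (observed in vivo but never quantified with
a generative model), deformable geometry, or drift beyond a constant
velocity. Passing tests therefore demonstrate correctness of the
estimators and pipelines on data satisfying the stated models — they do
not certify performance on real images with structured background,
varying spot brightness, or dense crossing tracks.

## Problem sizes

The test suite and acceptance script use 500 tracks × 100 frames for
per-class α medians, 300–500 tracks for ensemble-MSD oracles, a
20-track rendered movie (145×220×22 voxels × 30 frames) for the
end-to-end recovery check, 27 samples for the fusion-rate recovery, and
small constructed scenes elsewhere — sizes chosen so each check is
statistically decisive yet runs in seconds on one CPU.
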