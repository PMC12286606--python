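#!/usr/bin/env python
"""3D puncta counting, apical/basal classification, and staging.

Renders a synthetic neuromast-like scene with known apical and basal
puncta, runs the counting pipeline (threshold -> watershed ->
26-connected components -> size filter), classifies puncta against the
nucleus plane, and demonstrates kinocilium-height staging.

Finding: on a rendered scene with resolvable separations the count is
exact, and the apical/basal split matches the planted ground truth.
"""

import json
from pathlib import Path

import ribbonmotion as rm

OUT = Path("results/puncta")
SEED = 20240905


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    geometry = rm.CellGeometry((2.0, 3.0, 2.0), (12.0, 3.0, 2.0), 5.0)
    rp = rm.RenderParams(voxel_size=(0.1, 0.1, 0.2), psf_sigma=(0.15, 0.3),
                         stack_shape=(140, 60, 20), noise_model="poisson",
                         spot_amplitude=300.0, background=10.0)
    stack, truth = rm.make_puncta_scene(geometry, n_apical=4, n_basal=6, rp=rp,
                                        seed=SEED, min_separation_um=1.5)
    recs = rm.segment_puncta_3d(stack, intensity_threshold=60.0,
                                min_seed_separation_um=1.0)
    labeled, counts = rm.classify_apical_basal(recs, geometry)
    print(f"planted 4 apical + 6 basal; counted {counts['apical']} apical "
          f"+ {counts['basal']} basal ({len(recs)} total)")

    stages = {n: rm.stage_cell(n).stage for n in (2, 10, 30, 48)}
    for n, s in stages.items():
        print(f"kinocilium over {n} z-slices ({n * 0.425:.2f} um) -> {s}")
    (OUT / "counts.json").write_text(json.dumps(
        {"planted": {"apical": 4, "basal": 6}, "counted": counts,
         "staging_examples": stages}, indent=1))


if __name__ == "__main__":
    main()
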