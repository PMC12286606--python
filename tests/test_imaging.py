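"""Image-operation tests: registration, detection, counting, staging."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings
from hypothesis import strategies as st

import ribbonmotion as rm
from ribbonmotion.imaging import stage_from_height


def render(positions, shape=(80, 80, 20), noise="none", amplitude=200.0, background=10.0,
           voxel=(0.1, 0.1, 0.2), psf=(0.15, 0.3), seed=0):
    rp = rm.RenderParams(voxel_size=voxel, psf_sigma=psf, stack_shape=shape,
                         noise_model=noise, spot_amplitude=amplitude, background=background)
    return rm.render_stack(np.asarray(positions, dtype=float).reshape(-1, 3), rp, seed=seed)


class TestCorrectDrift:
    def test_constructed_shift_recovered(self):
        base = render([[1.5, 1.0, 0.9], [3.0, 2.5, 1.4]], shape=(100, 80, 14),
                      voxel=(0.05, 0.05, 0.18))
        frames = [base.data]
        for k in range(1, 4):
            frames.append(np.clip(ndi.shift(base.data, (0, 0, 3 * k), order=1), 0, None))
        mov = rm.ImageStack(np.stack(frames), base.voxel_size, dt=5.0)
        reg, off = rm.correct_drift(mov)
        expected = np.array([[0, 0, 0], [0, 0, -3], [0, 0, -6], [0, 0, -9]], dtype=float)
        assert np.allclose(off, expected, atol=0.5)
        # registered frames match the undrifted reference within 1 voxel
        for f in range(1, 4):
            com_ref = ndi.center_of_mass(reg.data[0] - 10.0)
            com_f = ndi.center_of_mass(np.clip(reg.data[f] - 10.0, 0, None))
            assert np.allclose(com_ref, com_f, atol=1.0)

    def test_identical_frames_zero_offsets(self):
        base = render([[2.0, 2.0, 1.0]])
        mov = rm.ImageStack(np.stack([base.data] * 3), base.voxel_size, dt=5.0)
        _, off = rm.correct_drift(mov)
        assert np.allclose(off, 0.0)

    def test_empty_frames_rejected(self):
        mov = rm.ImageStack(np.zeros((3, 4, 10, 10)), (0.1, 0.1, 0.2), dt=5.0)
        with pytest.raises(ValueError, match="register"):
            rm.correct_drift(mov)


class TestDetectSpots:
    def test_single_noiseless_spot_subvoxel_accuracy(self):
        st_ = render([[2.0, 2.0, 1.5]], shape=(100, 100, 18),
                     voxel=(0.04, 0.04, 0.17), psf=(0.1, 0.25))
        det = rm.detect_spots(st_, 0.427, quality_threshold=1.0)
        assert len(det) == 1
        # within half a voxel of the truth on every axis
        assert abs(det.x_um[0] - 2.0) < 0.02
        assert abs(det.y_um[0] - 2.0) < 0.02
        assert abs(det.z_um[0] - 1.5) < 0.085

    def test_empty_image_no_detections(self):
        st_ = rm.ImageStack(np.full((10, 40, 40), 5.0), (0.1, 0.1, 0.2))
        det = rm.detect_spots(st_, 0.5, quality_threshold=10.0)
        assert len(det) == 0

    def test_snr10_scene_detects_all_without_false_positives(self):
        rng = np.random.default_rng(5)
        pos = np.array([[1.0 + 1.3 * (i % 5), 1.0 + 1.3 * (i // 5), 0.8 + 0.2 * (i % 3)]
                        for i in range(20)])
        st_ = render(pos, shape=(80, 70, 14), noise="poisson", amplitude=300.0,
                     background=10.0, seed=3)
        det = rm.detect_spots(st_, 0.5, quality_threshold=60.0)
        assert len(det) == 20
        # every detection within 0.25 um of a planted spot
        d = np.linalg.norm(det[["x_um", "y_um", "z_um"]].to_numpy()[:, None, :]
                           - pos[None, :, :], axis=2)
        assert d.min(axis=1).max() < 0.25

    def test_subvoxel_diameter_rejected(self):
        st_ = rm.ImageStack(np.zeros((5, 10, 10)) + 1.0, (0.1, 0.1, 0.2))
        with pytest.raises(ValueError, match="smaller than one voxel"):
            rm.detect_spots(st_, 0.01)


class TestSegmentPuncta3D:
    def test_seven_well_separated_spots(self):
        pos = np.array([[1.5 + 1.5 * i, 2.0 + 0.5 * (i % 3), 1.0 + 0.3 * (i % 4)]
                        for i in range(5)] + [[2.0, 6.0, 3.0], [5.0, 6.5, 1.5]])
        st_ = render(pos, noise="poisson", seed=1)
        recs = rm.segment_puncta_3d(st_, 60.0, min_seed_separation_um=0.8)
        assert len(recs) == 7
        got = np.array([r.centroid_um for r in recs])
        d = np.linalg.norm(got[:, None, :] - pos[None, :, :], axis=2)
        assert d.min(axis=1).max() < 0.2

    def test_touching_pair_split_flag(self):
        # two spots 0.1 um apart, resolvable PSF: one object unsplit, two split
        pos = [[1.0, 1.0, 0.3], [1.1, 1.0, 0.3]]
        st_ = render(pos, shape=(100, 100, 6), voxel=(0.02, 0.02, 0.1),
                     psf=(0.03, 0.06), noise="none")
        merged = rm.segment_puncta_3d(st_, 60.0, split_touching=False)
        assert len(merged) == 1
        split = rm.segment_puncta_3d(st_, 60.0, split_touching=True,
                                     min_seed_separation_um=0.06)
        assert len(split) == 2

    def test_max_size_filter_excludes_huge_object(self):
        # constructed object of 200,000 voxels > the 183,500-voxel cap
        data = np.zeros((100, 100, 100))
        data[:20, :100, :100] = 50.0  # 200,000 voxels
        st_ = rm.ImageStack(data, (0.1, 0.1, 0.2))
        recs = rm.segment_puncta_3d(st_, 40.0, split_touching=False,
                                    max_size_vox=183_500)
        assert recs == []

    def test_min_max_size_ordering_enforced(self):
        st_ = rm.ImageStack(np.zeros((4, 4, 4)) + 1.0, (0.1, 0.1, 0.2))
        with pytest.raises(ValueError):
            rm.segment_puncta_3d(st_, 0.5, min_size_vox=10, max_size_vox=5)

    def test_threshold_monotonicity(self):
        st_ = render([[2.0, 2.0, 1.0], [5.0, 5.0, 2.0]], noise="poisson", seed=2)
        totals = []
        for thr in (30.0, 60.0, 90.0, 120.0):
            recs = rm.segment_puncta_3d(st_, thr, split_touching=False)
            totals.append(sum(r.volume_voxels for r in recs))
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestClassifyApicalBasal:
    def test_apex_and_base_points(self, geometry):
        apex = rm.PunctaRecord(tuple(geometry.apex_point), 1, 0.0)
        base = rm.PunctaRecord(tuple(geometry.base_point), 1, 0.0)
        labeled, counts = rm.classify_apical_basal([apex, base], geometry)
        assert labeled[0].compartment == "apical"
        assert labeled[1].compartment == "basal"
        assert counts == {"apical": 1, "basal": 1}

    def test_partition_property(self, geometry):
        rng = np.random.default_rng(0)
        recs = [rm.PunctaRecord(tuple(rng.uniform(0, 14, 3)), 1, 0.0) for _ in range(50)]
        _, counts = rm.classify_apical_basal(recs, geometry)
        assert counts["apical"] + counts["basal"] == 50


class TestQuantifyAreas2D:
    def test_gaussian_level_set_area(self):
        A, b, sig, thr = 200.0, 10.0, 0.1, 50.0
        st_ = render([[2.0, 2.0, 0.85]], shape=(200, 200, 10),
                     voxel=(0.02, 0.02, 0.17), psf=(sig, 0.25),
                     amplitude=A, background=b)
        areas = rm.quantify_areas_2d(st_, rolling_ball_radius_px=50, threshold=thr)
        analytic = np.pi * 2 * sig**2 * np.log(A / thr)
        assert len(areas) == 1
        assert areas[0] == pytest.approx(analytic, rel=0.15)

    def test_min_area_filter_strict(self):
        # a 2-pixel object at 0.02 um pixels: 0.0008 um^2 < 0.002 excluded;
        # a 3x3 object: 0.0036 um^2 kept
        data = np.zeros((1, 50, 50))
        data[0, 5, 5:7] = 100.0
        data[0, 20:23, 20:23] = 100.0
        st_ = rm.ImageStack(data, (0.02, 0.02, 0.17))
        areas = rm.quantify_areas_2d(st_, rolling_ball_radius_px=10, threshold=50.0,
                                     split_touching=False)
        assert areas == [pytest.approx(9 * 0.0004)]

    def test_flat_image_empty(self):
        st_ = rm.ImageStack(np.full((5, 40, 40), 7.0), (0.05, 0.05, 0.2))
        with pytest.warns(UserWarning):
            assert rm.quantify_areas_2d(st_, 10, threshold=5.0) == []

    def test_background_invariance(self):
        data = np.zeros((1, 60, 60))
        data[0, 20:26, 20:26] = 100.0
        low = rm.ImageStack(data, (0.05, 0.05, 0.2))
        high = rm.ImageStack(data + 20.0, (0.05, 0.05, 0.2))
        a_low = rm.quantify_areas_2d(low, rolling_ball_radius_px=15, threshold=50.0,
                                     split_touching=False)
        a_high = rm.quantify_areas_2d(high, rolling_ball_radius_px=15, threshold=50.0,
                                      split_touching=False)
        assert a_low == a_high


class TestStaging:
    @pytest.mark.parametrize(
        "n_slices,expected_stage,expected_height",
        [
            (10, "intermediate", 4.25),
            (2, "early", 0.85),
            (48, "mature", 20.4),
            (0, "early", 0.0),
            (3, "early", 1.275),     # 1.275 < 1.5
            (24, "late", 10.2),
            (42, "late", 17.85),     # 17.85 <= 18 still late
            (43, "mature", 18.275),
        ],
    )
    def test_staging_bins(self, n_slices, expected_stage, expected_height):
        lab = rm.stage_cell(n_slices)
        assert lab.stage == expected_stage
        assert lab.kinocilium_height_um == pytest.approx(expected_height)

    def test_boundary_heights(self):
        assert stage_from_height(1.5) == "intermediate"   # [1.5, 10)
        assert stage_from_height(10.0) == "late"          # [10, 18]
        assert stage_from_height(18.0) == "late"
        assert stage_from_height(18.0 + 1e-9) == "mature"

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    def test_stage_total_function(self, h):
        assert stage_from_height(h) in {"early", "intermediate", "late", "mature"}

    def test_negative_slices_rejected(self):
        with pytest.raises(ValueError):
            rm.stage_cell(-1)
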