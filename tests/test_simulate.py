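"""Simulator tests: closed-form oracles and determinism.

Expected values used here come from the closed forms of the motion
models: a noiseless ballistic track lies exactly on r(t) = v t d, free
diffusion has per-axis increment variance 2 D dt and 3D MSD 6 D tau,
and reflected diffusion in a sphere of radius R has the stationary
plateau E|X - Y|^2 = 6 R^2 / 5 for X, Y independent uniform in the
ball (cross-checked by Monte Carlo below).
"""

import numpy as np
import pytest

import ribbonmotion as rm
from ribbonmotion.motion import ensemble_msd


def brownian_params(**kw):
    base = dict(model="brownian", D=0.01, sigma_loc=0.0, dt=5.0, n_frames=100)
    base.update(kw)
    return rm.MotionParams(**base)


class TestSimulateTrack:
    def test_noiseless_ballistic_positions_exact(self):
        p = rm.MotionParams(model="directed", v=0.1, D=0.0, direction=(1, 0, 0),
                            sigma_loc=0.0, dt=10.0, n_frames=8)
        tr = rm.simulate_track(p)
        # v*dt = 1 um per frame along x
        assert np.allclose(tr.xyz, np.c_[np.arange(8.0), np.zeros(8), np.zeros(8)])

    def test_brownian_increment_variance_matches_2Ddt(self):
        p = brownian_params(D=0.01, dt=5.0, n_frames=10_001)
        tr = rm.simulate_track(p, rng=np.random.default_rng(0))
        inc = np.diff(tr.xyz, axis=0)
        assert inc.var(axis=0) == pytest.approx([0.1, 0.1, 0.1], rel=0.05)

    def test_confined_never_leaves_corral(self):
        p = rm.MotionParams(model="confined", D=0.05, R_conf=0.5, sigma_loc=0.0,
                            dt=5.0, n_frames=400)
        tr = rm.simulate_track(p, start=(3, 3, 3), rng=np.random.default_rng(1))
        r = np.linalg.norm(tr.xyz - np.array([3.0, 3.0, 3.0]), axis=1)
        assert r.max() <= 0.5 + 1e-12

    def test_seed_determinism(self):
        p = brownian_params(seed=77)
        a = rm.simulate_track(p)
        b = rm.simulate_track(p)
        assert np.array_equal(a.xyz, b.xyz)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            rm.MotionParams(model="levy", dt=5.0, n_frames=10)
        with pytest.raises(ValueError):
            rm.MotionParams(model="brownian", dt=5.0, n_frames=1)
        with pytest.raises(ValueError):
            rm.MotionParams(model="confined", dt=5.0, n_frames=10)  # no R_conf
        with pytest.raises(ValueError):
            rm.MotionParams(model="directed", v=0.1, dt=5.0, n_frames=10)  # no direction


class TestEnsembleOracles:
    def test_brownian_ensemble_msd_is_6_D_tau(self):
        D, dt = 0.01, 5.0
        mix = [(brownian_params(D=D, dt=dt, n_frames=40), 500)]
        ts = rm.simulate_trackset(mix, seed=11).tracks
        lags, msd = ensemble_msd(ts)
        short = lags <= 0.25 * lags.max()
        assert msd[short] == pytest.approx(6 * D * lags[short], rel=0.05)

    def test_confined_plateau_matches_two_uniform_points_monte_carlo(self):
        R = 0.4
        p = rm.MotionParams(model="confined", D=0.05, R_conf=R, sigma_loc=0.0,
                            dt=5.0, n_frames=60)
        ts = rm.simulate_trackset([(p, 300)], seed=13).tracks
        lags, msd = ensemble_msd(ts)
        plateau = msd[lags >= 0.5 * lags.max()].mean()
        # independent oracle: E|X-Y|^2 for X, Y uniform in the ball
        rng = np.random.default_rng(99)
        pts = rng.standard_normal((2, 200_000, 3))
        radii = rng.random((2, 200_000)) ** (1 / 3) * R
        pts = pts / np.linalg.norm(pts, axis=2, keepdims=True) * radii[:, :, None]
        mc = float(((pts[0] - pts[1]) ** 2).sum(axis=1).mean())
        assert mc == pytest.approx(6 * R**2 / 5, rel=0.01)  # closed form sanity
        assert plateau == pytest.approx(mc, rel=0.10)

    def test_ballistic_msd_is_v2_tau2_exactly(self):
        p = rm.MotionParams(model="directed", v=0.1, D=0.0, direction=(0, 1, 0),
                            sigma_loc=0.0, dt=5.0, n_frames=20)
        prof = rm.compute_msd(rm.simulate_track(p))
        assert prof.msd_um2 == pytest.approx((0.1 * prof.lags_s) ** 2, abs=1e-12)


class TestTrackset:
    def test_mixture_counts_and_labels(self):
        mix = [(brownian_params(n_frames=12), 5),
               (rm.MotionParams(model="directed", v=0.1, direction=(1, 0, 0),
                                dt=5.0, n_frames=12), 3)]
        lts = rm.simulate_trackset(mix, seed=3)
        assert len(lts) == 8
        labels = list(lts.labels.values())
        assert labels.count("brownian") == 5 and labels.count("directed") == 3

    def test_same_seed_identical_tables(self):
        mix = [(brownian_params(n_frames=15), 4)]
        a = rm.simulate_trackset(mix, seed=5).tracks.to_dataframe()
        b = rm.simulate_trackset(mix, seed=5).tracks.to_dataframe()
        assert a.equals(b)

    def test_empty_mixture_rejected(self):
        with pytest.raises(ValueError):
            rm.simulate_trackset([], seed=0)

    def test_directed_toward_base_agrees_with_polarity(self, geometry):
        d = np.append(geometry.axis_xy, 0.0)
        mix = [(rm.MotionParams(model="directed", v=0.05, D=0.001, direction=d,
                                sigma_loc=0.0, dt=5.0, n_frames=30), 10)]
        lts = rm.simulate_trackset(mix, geometry=geometry, seed=8)
        for tr in lts.tracks:
            assert rm.track_angle(tr, geometry).angle_deg < 90.0


class TestCometField:
    def test_zero_jitter_full_base_fraction(self, geometry):
        f = rm.simulate_comet_field(geometry, n=20, p_base=1.0, jitter_deg=0.0, seed=2)
        for tr in f.tracks:
            assert rm.track_angle(tr, geometry).angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_lifetime_controls_track_length(self, geometry):
        f = rm.simulate_comet_field(geometry, n=10, lifetime_frames=6, seed=0)
        assert all(tr.n_points == 6 for tr in f.tracks)

    def test_base_fraction_within_99pct_binomial_interval(self, geometry):
        from scipy.stats import binom
        n, p = 2598, 0.8
        f = rm.simulate_comet_field(geometry, n=n, p_base=p, seed=6)
        k = sum(lab == "base" for lab in f.labels.values())
        lo, hi = binom.ppf([0.005, 0.995], n, p)
        assert lo <= k <= hi

    def test_labels_match_realized_direction(self, geometry):
        f = rm.simulate_comet_field(geometry, n=50, p_base=0.5, jitter_deg=5.0, seed=4)
        for tr in f.tracks:
            ang = rm.track_angle(tr, geometry).angle_deg
            assert (ang < 90) == (f.labels[tr.track_id] == "base")


class TestFusionPair:
    def test_tracks_coincide_from_meet_frame(self):
        a, b, ev = rm.simulate_fusion_pair(meet_frame=5, post_frames=6, dt=50.0)
        post = slice(5, None)
        assert np.allclose(a.xyz[post], b.xyz[post])
        assert ev.merge_frame == 5
        d_before = np.linalg.norm(a.xyz[:5] - b.xyz[:5], axis=1)
        assert np.all(d_before > 0)

    def test_crossing_returns_no_ground_truth(self):
        a, b, ev = rm.simulate_fusion_pair(meet_frame=5, post_frames=0, dt=50.0)
        assert ev is None
        assert np.linalg.norm(a.xyz[-1] - b.xyz[-1]) > 0


class TestRendering:
    def test_single_spot_maximum_at_spot_voxel(self):
        rp = rm.RenderParams(voxel_size=(0.1, 0.1, 0.2), psf_sigma=(0.15, 0.3),
                             stack_shape=(40, 40, 10), noise_model="none")
        st = rm.render_stack(np.array([[2.0, 1.0, 1.0]]), rp)
        z, y, x = np.unravel_index(np.argmax(st.data), st.data.shape)
        assert (x, y, z) == (20, 10, 5)

    def test_no_spots_constant_background(self):
        rp = rm.RenderParams(voxel_size=(0.1, 0.1, 0.2), psf_sigma=(0.15, 0.3),
                             stack_shape=(20, 20, 5), noise_model="none", background=7.0)
        st = rm.render_stack(np.empty((0, 3)), rp)
        assert np.all(st.data == 7.0)

    def test_out_of_bounds_position_rejected(self):
        rp = rm.RenderParams(stack_shape=(10, 10, 5), noise_model="none")
        with pytest.raises(ValueError, match="outside"):
            rm.render_stack(np.array([[99.0, 0.1, 0.1]]), rp)

    def test_render_and_count_recovers_spots(self):
        rp = rm.RenderParams(voxel_size=(0.1, 0.1, 0.2), psf_sigma=(0.15, 0.3),
                             stack_shape=(80, 80, 20), noise_model="poisson",
                             spot_amplitude=200.0, background=10.0)
        pos = np.array([[1.5 + 1.5 * i, 2.0 + 0.5 * (i % 3), 1.0 + 0.3 * (i % 4)]
                        for i in range(5)] + [[2.0, 6.0, 3.0], [5.0, 6.5, 1.5]])
        st = rm.render_stack(pos, rp, seed=1)
        recs = rm.segment_puncta_3d(st, 60.0, min_seed_separation_um=0.8)
        assert len(recs) == 7


class TestPunctaScene:
    def test_ground_truth_compartments(self, geometry):
        rp = rm.RenderParams(voxel_size=(0.1, 0.1, 0.2), psf_sigma=(0.15, 0.3),
                             stack_shape=(140, 60, 20), noise_model="none")
        _, truth = rm.make_puncta_scene(geometry, 3, 4, rp, seed=5)
        _, counts = rm.classify_apical_basal(truth, geometry)
        assert counts == {"apical": 3, "basal": 4}

    def test_empty_scene(self, geometry):
        rp = rm.RenderParams(voxel_size=(0.1, 0.1, 0.2), psf_sigma=(0.15, 0.3),
                             stack_shape=(140, 60, 20), noise_model="none", background=3.0)
        st, truth = rm.make_puncta_scene(geometry, 0, 0, rp, seed=5)
        assert truth == []
        assert np.all(st.data == 3.0)

    def test_impossible_scene_raises(self, geometry):
        rp = rm.RenderParams(voxel_size=(0.1, 0.1, 0.2), psf_sigma=(0.15, 0.3),
                             stack_shape=(20, 20, 8), noise_model="none")
        with pytest.raises(ValueError, match="too small"):
            rm.make_puncta_scene(geometry, 40, 40, rp, seed=0, min_separation_um=1.0)
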