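import dataclasses

import numpy as np
import pytest
from scipy import interpolate
from scipy.spatial import cKDTree

import cochlea3d as c3
from cochlea3d import phantom as ph
from cochlea3d.centerline import extend_polyline_to_data


class TestInit:
    def test_degenerate_mirror_collapses_pairs(self):
        spec = dataclasses.replace(ph.default_phantom(), scala_separation=0.0)
        model = c3.init_mirrored_gmm(spec, 8, 0.1)
        assert np.allclose(model.means_sv, model.means_st, atol=1e-12)

    def test_weights_normalized(self):
        model = c3.init_mirrored_gmm(ph.default_phantom(), 13, 0.1)
        assert abs(2 * model.pair_weights.sum() - 1.0) < 1e-12

    def test_means_lie_on_analytic_offset_curves(self):
        spec = ph.default_phantom()
        model = c3.init_mirrored_gmm(spec, 8, 0.1)
        sv, st = ph.scala_offset_curves(spec, np.linspace(0, 1, 8))
        assert np.abs(model.means_sv - sv).max() < 1e-9
        assert np.abs(model.means_st - st).max() < 1e-9

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            c3.init_mirrored_gmm(ph.default_phantom(), 1, 0.1)
        with pytest.raises(ValueError):
            c3.init_mirrored_gmm(ph.default_phantom(), 4, -1.0)


class TestFit:
    def test_exact_means_are_a_fixed_point(self):
        spec = ph.default_phantom()
        model = c3.init_mirrored_gmm(spec, 8, 1e-4)
        cloud = ph.PointCloud(
            np.vstack([model.means_sv, model.means_st]),
            np.array(["SV"] * 8 + ["ST"] * 8))
        fitted, _ = c3.fit_gmm(model, cloud, c3.FitConfig(max_iterations=1))
        assert np.abs(fitted.means_sv - model.means_sv).max() < 1e-9
        assert np.abs(fitted.means_st - model.means_st).max() < 1e-9

    def test_pinned_locals_recover_global_translation(self):
        spec = ph.default_phantom()
        m = 16
        model = c3.init_mirrored_gmm(spec, m, 0.05)
        sv, st = ph.scala_offset_curves(spec, np.linspace(0, 1, m))
        pts = np.vstack([np.repeat(sv, 5, axis=0),
                         np.repeat(st, 5, axis=0)]) + np.array([5.0, 0, 0])
        cloud = ph.PointCloud(pts, np.array(["SV"] * (5 * m)
                                            + ["ST"] * (5 * m)))
        fitted, _ = c3.fit_gmm(model, cloud, c3.FitConfig(
            max_iterations=50, local_affine_regularization=1e12,
            tolerance=1e-14))
        a_mat, b = fitted.global_affine
        assert np.abs(b - np.array([5.0, 0.0, 0.0])).max() < 1e-3
        assert np.abs(a_mat - np.eye(3)).max() < 1e-3

    def test_recovers_from_inflated_init_radius(self):
        spec = ph.default_phantom()
        cloud, mid = ph.generate_scala_cloud(spec, 4000, 0.0, seed=2)
        bad = dataclasses.replace(spec, radius_base=spec.radius_base * 1.1,
                                  radius_apex=spec.radius_apex * 1.1)
        model = c3.init_mirrored_gmm(bad, 64, 0.1)
        fitted, _ = c3.fit_gmm(model, cloud,
                               c3.FitConfig(max_iterations=80))
        d, _ = cKDTree(mid).query(fitted.midpoints())
        assert d.mean() < 0.1 * spec.tube_radius

    def test_loglik_trace_monotone(self, fitted_model):
        _, trace = fitted_model
        assert np.all(np.diff(trace) >= -1e-8)

    def test_translation_equivariance(self):
        spec = ph.default_phantom()
        cloud, _ = ph.generate_scala_cloud(spec, 800, 0.08, seed=5)
        model = c3.init_mirrored_gmm(spec, 16, 0.1)
        cfg = c3.FitConfig(max_iterations=15)
        f0, _ = c3.fit_gmm(model, cloud, cfg)
        v = np.array([2.0, -1.0, 3.0])
        shifted_model = c3.MirroredGMM(
            means_sv=model.means_sv + v, means_st=model.means_st + v,
            variance=model.variance, pair_weights=model.pair_weights)
        shifted_cloud = ph.PointCloud(cloud.points + v, cloud.labels)
        f1, _ = c3.fit_gmm(shifted_model, shifted_cloud, cfg)
        assert np.abs(f1.means_sv - (f0.means_sv + v)).max() < 1e-6
        assert np.abs(f1.means_st - (f0.means_st + v)).max() < 1e-6

    def test_starved_pair_is_frozen_not_deleted(self):
        spec = ph.default_phantom()
        model = c3.init_mirrored_gmm(spec, 8, 0.01)
        # push one pair far away so no point claims it
        far = model.means_sv.copy()
        far[3] += 500.0
        far_st = model.means_st.copy()
        far_st[3] += 500.0
        broken = c3.MirroredGMM(means_sv=far, means_st=far_st,
                                variance=model.variance,
                                pair_weights=model.pair_weights)
        cloud = ph.PointCloud(
            np.vstack([model.means_sv, model.means_st]),
            np.array(["SV"] * 8 + ["ST"] * 8))
        fitted, trace = c3.fit_gmm(broken, cloud,
                                   c3.FitConfig(max_iterations=5))
        assert fitted.frozen[3]
        # the pair may move rigidly with the centroid pre-alignment of the
        # whole model, but must not drift toward the data afterwards
        shift = 0.5 * ((cloud.subset("SV").mean(axis=0)
                        - far.mean(axis=0))
                       + (cloud.subset("ST").mean(axis=0)
                          - far_st.mean(axis=0)))
        assert np.abs(fitted.means_sv[3] - (far[3] + shift)).max() < 1e-9
        assert np.abs(fitted.means_st[3] - (far_st[3] + shift)).max() < 1e-9
        assert np.all(np.diff(trace) >= -1e-8)

    def test_empty_or_one_sided_cloud_rejected(self):
        model = c3.init_mirrored_gmm(ph.default_phantom(), 4, 0.1)
        with pytest.raises(ValueError):
            c3.fit_gmm(model, ph.PointCloud(np.zeros((0, 3)),
                                            np.array([], dtype=str)))
        one_sided = ph.PointCloud(np.zeros((5, 3)), np.array(["SV"] * 5))
        with pytest.raises(ValueError):
            c3.fit_gmm(model, one_sided)


class TestExtractAndAverage:
    def test_polyline_lengths_match_pair_count(self, fitted_model):
        fitted, _ = fitted_model
        sv, st = c3.extract_scala_centerlines(fitted)
        assert len(sv) == len(st) == fitted.n_pairs

    def test_fresh_model_polylines_equal_offset_curves(self):
        spec = ph.default_phantom()
        model = c3.init_mirrored_gmm(spec, 10, 0.1)
        sv, st = c3.extract_scala_centerlines(model)
        esv, est = ph.scala_offset_curves(spec, np.linspace(0, 1, 10))
        assert np.allclose(sv, esv) and np.allclose(st, est)

    def test_average_of_identical_curves_is_identity(self):
        line = np.random.default_rng(0).uniform(0, 1, (12, 3))
        assert np.array_equal(c3.average_centerlines(line, line), line)

    def test_average_symmetric_offsets_cancel(self):
        z = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
        off = np.array([1.0, 0.0, 0.0])
        avg = c3.average_centerlines(z + off, z - off)
        assert np.array_equal(avg, z)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            c3.average_centerlines(np.zeros((5, 3)), np.zeros((4, 3)))

    def test_fitted_scala_polylines_track_generator_curves(
            self, default_spec, fitted_model):
        fitted, _ = fitted_model
        sv, st = c3.extract_scala_centerlines(fitted)
        gt_sv, gt_st = ph.scala_offset_curves(default_spec,
                                              np.linspace(0, 1, 20000))
        for poly, gt in ((sv, gt_sv), (st, gt_st)):
            d, _ = cKDTree(gt).query(poly)
            assert d.mean() < 0.15 * default_spec.tube_radius


class TestBuildCenterline:
    def test_straight_segment_stations_and_tangents(self):
        pts = np.column_stack([np.linspace(0, 10, 10), np.zeros(10),
                               np.zeros(10)])
        line = c3.build_centerline(pts, 5)
        assert np.allclose(line.stations[:, 0], [0, 2.5, 5, 7.5, 10],
                           atol=1e-6)
        assert np.allclose(line.tangents, [1, 0, 0], atol=1e-9)

    def test_quarter_circle_middle_station_at_45_degrees(self):
        th = np.linspace(0, np.pi / 2, 50)
        pts = np.column_stack([np.cos(th), np.sin(th), np.zeros(50)])
        line = c3.build_centerline(pts, 3)
        ang = np.rad2deg(np.arctan2(line.stations[1, 1],
                                    line.stations[1, 0]))
        assert abs(ang - 45.0) < 0.1

    def test_station_gaps_uniform_on_helix(self):
        spec = ph.default_phantom()
        pts = ph.helix_curve(spec, np.linspace(0, 1, 100))
        line = c3.build_centerline(pts, 200)
        # independent quadrature of gap lengths between station parameters
        gaps = []
        for u0, u1 in zip(line.station_params[:-1], line.station_params[1:]):
            uu = np.linspace(u0, u1, 64)
            pp = np.asarray(interpolate.splev(uu, line.tck)).T
            gaps.append(np.linalg.norm(np.diff(pp, axis=0), axis=1).sum())
        gaps = np.asarray(gaps)
        assert gaps.std() / gaps.mean() < 1e-3

    def test_duplicates_deduplicated_with_warning(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0.5, 0],
                        [3, 0, 0], [4, 0.5, 0]], dtype=float)
        with pytest.warns(UserWarning, match="duplicate"):
            line = c3.build_centerline(pts, 4)
        assert len(line.control_points) == 5

    def test_too_few_unique_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0]],
                       dtype=float)
        with pytest.raises(ValueError):
            c3.build_centerline(pts, 4)

    def test_tangents_unit_norm(self, default_spec):
        pts = ph.helix_curve(default_spec, np.linspace(0, 1, 60))
        line = c3.build_centerline(pts, 100)
        assert np.abs(np.linalg.norm(line.tangents, axis=1) - 1).max() < 1e-9

    def test_json_roundtrip(self, tmp_path, default_spec):
        pts = ph.helix_curve(default_spec, np.linspace(0, 1, 30))
        line = c3.build_centerline(pts, 20)
        f = tmp_path / "line.json"
        line.to_json(f)
        import json
        with open(f) as fh:
            payload = json.load(fh)
        assert np.allclose(payload["stations"], line.stations)
        assert payload["arc_length"] == pytest.approx(line.arc_length)


class TestEndExtension:
    def test_straight_tube_end_recovered(self):
        # cylinder of radius 0.4 along z over [0, 10]; polyline stops at 8.5
        rng = np.random.default_rng(4)
        n = 4000
        z = rng.uniform(0, 10, n)
        ang = rng.uniform(0, 2 * np.pi, n)
        rad = 0.4 * np.sqrt(rng.uniform(0, 1, n))
        pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang), z])
        poly = np.column_stack([np.zeros(8), np.zeros(8),
                                np.linspace(0.8, 8.5, 8)])
        out = extend_polyline_to_data(poly, pts, noise_sigma=0.05,
                                      capture_radius=0.7)
        assert len(out) == 10  # both ends extended
        assert abs(out[-1][2] - 10.0) < 0.25
        assert abs(out[0][2] - 0.0) < 0.25
        # lateral position is refined from the data; stays on the axis up
        # to the sampling error of the local perpendicular mean
        assert np.abs(out[[0, -1], :2]).max() < 0.05

    def test_no_extension_when_polyline_covers_data(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(0, 10, 2000)
        pts = np.column_stack([np.zeros(2000), np.zeros(2000), z])
        poly = np.column_stack([np.zeros(12), np.zeros(12),
                                np.linspace(-0.5, 10.5, 12)])
        out = extend_polyline_to_data(poly, pts, noise_sigma=0.01,
                                      capture_radius=0.6)
        assert len(out) == len(poly)
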