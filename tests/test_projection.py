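import numpy as np
import pytest

import cochlea3d as c3
from cochlea3d import phantom as ph
from cochlea3d import projection as pj


def circle_contour(r=1.0, k=64, label="ring", center=(0.0, 0.0)):
    a = np.linspace(0, 2 * np.pi, k, endpoint=False)
    return pj.Contour2D(label, np.column_stack([center[0] + r * np.cos(a),
                                                center[1] + r * np.sin(a)]))


@pytest.fixture(scope="module")
def helix_line(default_spec):
    pts = ph.helix_curve(default_spec, np.linspace(0, 1, 100))
    return c3.build_centerline(pts, 200)


@pytest.fixture(scope="module")
def helix_frames(default_spec, helix_line):
    return pj.build_frames(helix_line, default_spec.axis)


class TestContourArea:
    def test_square(self):
        sq = pj.Contour2D("sq", [[0, 0], [10, 0], [10, 10], [0, 10]])
        assert pj.contour_area(sq) == pytest.approx(100.0)

    def test_polygon_approximates_circle(self):
        c = circle_contour(r=10.0, k=360)
        assert pj.contour_area(c) == pytest.approx(np.pi * 100, rel=1e-3)

    def test_orientation_invariant(self):
        sq = pj.Contour2D("sq", [[0, 0], [10, 0], [10, 10], [0, 10]])
        rev = pj.Contour2D("sq", sq.points[::-1])
        assert pj.contour_area(sq) == pj.contour_area(rev)

    def test_open_contour_rejected(self):
        open_c = pj.Contour2D("bm", [[0, 0], [1, 1]], closed=False)
        with pytest.raises(ValueError, match="open"):
            pj.contour_area(open_c)

    def test_self_intersection_rejected(self):
        bowtie = pj.Contour2D("x", [[0, 0], [2, 2], [2, 0], [0, 2]])
        with pytest.raises(ValueError, match="self-intersecting"):
            pj.contour_area(bowtie)


class TestScaleProfile:
    def test_equal_areas_give_unit_scale(self, helix_line):
        areas = {"a": 3.0, "b": 5.0}
        prof = pj.estimate_scale_profile(areas, areas, areas, helix_line)
        assert np.allclose(prof.scales, 1.0)

    def test_sqrt_and_linear_midpoint(self):
        pts = np.column_stack([np.linspace(0, 10, 10), np.zeros(10),
                               np.zeros(10)])
        line = c3.build_centerline(pts, 3)
        prof = pj.estimate_scale_profile({"a": 1.0}, {"a": 4.0}, {"a": 1.0},
                                         line)
        assert np.allclose(prof.scales, [2.0, 1.5, 1.0])

    def test_endpoints_and_affinity(self, helix_line):
        prof = pj.estimate_scale_profile({"a": 2.0}, {"a": 5.0}, {"a": 1.0},
                                         helix_line)
        assert prof.scales[0] == pytest.approx(np.sqrt(2.5), abs=0)
        assert prof.scales[-1] == pytest.approx(np.sqrt(0.5), abs=0)
        second = np.diff(prof.scales, 2)
        assert np.abs(second).max() < 1e-12

    def test_no_common_label_rejected(self, helix_line):
        with pytest.raises(ValueError, match="common"):
            pj.estimate_scale_profile({"a": 1.0}, {"b": 1.0}, {"b": 1.0},
                                      helix_line)

    def test_nonpositive_area_rejected(self, helix_line):
        with pytest.raises(ValueError, match="non-positive"):
            pj.estimate_scale_profile({"a": 0.0}, {"a": 1.0}, {"a": 1.0},
                                      helix_line)

    def test_phantom_base_apex_ratio_recovered(self):
        # sections rendered from tubes whose base radius is twice the apex
        sp = 0.016
        base_r, apex_r = 25.0, 12.5
        base = ph.SectionSpec(pixel_spacing=sp, structures=[
            ("lumen", ph.Disk((128, 128), base_r))])
        apex = ph.SectionSpec(pixel_spacing=sp, structures=[
            ("lumen", ph.Disk((128, 128), apex_r))])
        _, anno_b, _ = ph.render_section(base)
        _, anno_a, _ = ph.render_section(apex)
        hist = {"lumen": pj.contour_area(anno_a["lumen"])}
        areas_b = {"lumen": pj.contour_area(anno_b["lumen"])}
        areas_a = {"lumen": pj.contour_area(anno_a["lumen"])}
        pts = np.column_stack([np.linspace(0, 10, 10), np.zeros(10),
                               np.zeros(10)])
        line = c3.build_centerline(pts, 5)
        prof = pj.estimate_scale_profile(hist, areas_b, areas_a, line)
        assert prof.s_max / prof.s_min == pytest.approx(2.0, rel=0.02)


class TestFrames:
    def test_straight_centerline_constant_frame(self):
        pts = np.column_stack([np.zeros(10), np.zeros(10),
                               np.linspace(0, 10, 10)])
        line = c3.build_centerline(pts, 20)
        fr = pj.build_frames(line, (1.0, 0.0, 0.0))
        assert np.allclose(fr.tangents, [0, 0, 1], atol=1e-9)
        assert np.allclose(fr.normals1, [1, 0, 0], atol=1e-9)
        assert np.allclose(fr.normals2, [0, 1, 0], atol=1e-9)

    def test_frames_orthonormal_right_handed(self, helix_frames):
        t, n1, n2 = (helix_frames.tangents, helix_frames.normals1,
                     helix_frames.normals2)
        assert np.abs(np.einsum("ij,ij->i", t, n1)).max() < 1e-9
        assert np.abs(np.einsum("ij,ij->i", t, n2)).max() < 1e-9
        assert np.abs(np.linalg.norm(n1, axis=1) - 1).max() < 1e-9
        det = np.einsum("ij,ij->i", np.cross(t, n1), n2)
        assert np.abs(det - 1).max() < 1e-9

    def test_no_flips_along_spiral(self, helix_frames):
        n1, t = helix_frames.normals1, helix_frames.tangents
        turn_n1 = np.arccos(np.clip(
            np.einsum("ij,ij->i", n1[:-1], n1[1:]), -1, 1))
        turn_t = np.arccos(np.clip(
            np.einsum("ij,ij->i", t[:-1], t[1:]), -1, 1))
        assert turn_n1.max() < 2 * turn_t.max() + 1e-6

    def test_matches_finite_difference_transport_oracle(self):
        # quarter circle: transport the initial normal by successive
        # minimal rotations between consecutive tangents
        th = np.linspace(0, np.pi / 2, 80)
        pts = np.column_stack([np.cos(th), np.sin(th), np.zeros(80)])
        line = c3.build_centerline(pts, 60)
        fr = pj.build_frames(line, (0.0, 0.0, 1.0))
        n = np.array([0.0, 0.0, 1.0])
        worst = 0.0
        for i in range(len(line.tangents) - 1):
            t0, t1 = line.tangents[i], line.tangents[i + 1]
            axis = np.cross(t0, t1)
            s = np.linalg.norm(axis)
            if s > 1e-15:
                axis = axis / s
                ang = np.arctan2(s, t0 @ t1)
                n = (n * np.cos(ang) + np.cross(axis, n) * np.sin(ang)
                     + axis * (axis @ n) * (1 - np.cos(ang)))
            dev = np.arccos(np.clip(abs(n @ fr.normals1[i + 1]), -1, 1))
            worst = max(worst, np.rad2deg(dev))
        assert worst < 0.1

    def test_parallel_reference_rejected(self):
        pts = np.column_stack([np.zeros(10), np.zeros(10),
                               np.linspace(0, 10, 10)])
        line = c3.build_centerline(pts, 5)
        with pytest.raises(ValueError, match="parallel"):
            pj.build_frames(line, (0.0, 0.0, 1.0))


class TestProjection:
    def test_anchor_maps_to_station(self, helix_line, helix_frames):
        prof = pj.ScaleProfile.constant(3.7, len(helix_line.stations))
        contour = pj.Contour2D("p", [[2.0, 5.0], [2.0, 6.0], [3.0, 5.0]])
        ring = pj.project_contour(contour, 17, helix_line, helix_frames,
                                  prof, in_plane_offset=(2.0, 5.0))
        assert np.allclose(ring[0], helix_line.stations[17], atol=1e-12)

    def test_axis_aligned_embedding(self):
        pts = np.column_stack([np.zeros(10), np.zeros(10),
                               np.linspace(0, 10, 10)])
        line = c3.build_centerline(pts, 5)
        fr = pj.build_frames(line, (1.0, 0.0, 0.0))
        prof = pj.ScaleProfile.constant(1.0, 5)
        contour = pj.Contour2D("c", [[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        ring = pj.project_contour(contour, 2, line, fr, prof)
        assert np.allclose(ring[0], [1, 0, 5], atol=1e-9)
        assert np.allclose(ring[1], [0, 1, 5], atol=1e-9)

    def test_similarity_scales_pairwise_distances(self, helix_line,
                                                  helix_frames):
        rng = np.random.default_rng(8)
        pts2d = rng.uniform(-2, 2, (15, 2))
        contour = pj.Contour2D("c", pts2d)
        prof = pj.ScaleProfile.constant(2.0, len(helix_line.stations))
        ring = pj.project_contour(contour, 123, helix_line, helix_frames,
                                  prof, in_plane_offset=(0.3, -0.4))
        d2 = np.linalg.norm(pts2d[:, None] - pts2d[None, :], axis=-1)
        d3 = np.linalg.norm(ring[:, None] - ring[None, :], axis=-1)
        nz = d2 > 0
        assert np.abs(d3[nz] / d2[nz] - 2.0).max() < 1e-9


class TestSweep:
    def test_single_station_sweep_equals_projection(self, helix_line,
                                                    helix_frames):
        prof = pj.ScaleProfile.constant(1.0, len(helix_line.stations))
        contour = circle_contour()
        curve = pj.sweep_structure(contour, helix_line, helix_frames, prof,
                                   station_range=(7, 7))
        ring = pj.project_contour(contour, 7, helix_line, helix_frames, prof)
        assert curve.rings.shape == (1, 64, 3)
        assert np.array_equal(curve.rings[0], ring)

    def test_translational_sweep_on_straight_centerline(self):
        pts = np.column_stack([np.zeros(10), np.zeros(10),
                               np.linspace(0, 10, 10)])
        line = c3.build_centerline(pts, 6)
        fr = pj.build_frames(line, (1.0, 0.0, 0.0))
        prof = pj.ScaleProfile.constant(1.0, 6)
        curve = pj.sweep_structure(circle_contour(), line, fr, prof)
        first = curve.rings[0]
        for ring in curve.rings[1:]:
            delta = ring - first
            assert np.abs(delta - delta[0]).max() < 1e-9

    def test_rings_orthogonal_to_tangents(self, helix_line, helix_frames):
        prof = pj.ScaleProfile.constant(1.0, len(helix_line.stations))
        curve = pj.sweep_structure(circle_contour(r=0.4), helix_line,
                                   helix_frames, prof)
        for i in (0, 50, 120, 199):
            rel = curve.rings[i] - helix_line.stations[i]
            proj = rel @ helix_line.tangents[i]
            assert np.abs(proj).max() < 1e-9

    def test_invalid_station_range(self, helix_line, helix_frames):
        prof = pj.ScaleProfile.constant(1.0, len(helix_line.stations))
        with pytest.raises(ValueError):
            pj.sweep_structure(circle_contour(), helix_line, helix_frames,
                               prof, station_range=(5, 1000))


class TestAnnotationIO:
    def test_json_roundtrip(self, tmp_path):
        anno = pj.AnnotationSet("s1", 0.02, [
            circle_contour(r=2.0, label="scala vestibuli"),
            pj.Contour2D("basilar membrane", [[0, 0], [4, 1]], closed=False),
        ])
        f = tmp_path / "anno.json"
        anno.to_json(f)
        back = pj.AnnotationSet.from_json(f)
        assert back.slice_id == "s1"
        assert back.pixel_spacing == 0.02
        assert back.labels == anno.labels
        for a, b in zip(anno.contours, back.contours):
            assert np.allclose(a.points, b.points)
            assert a.closed == b.closed

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pj.AnnotationSet("s", 1.0, [circle_contour(label="x"),
                                        circle_contour(label="x")])

    def test_contour_invariants(self):
        with pytest.raises(ValueError):
            pj.Contour2D("c", [[0, 0], [1, 1]], closed=True)
        with pytest.raises(ValueError):
            pj.Contour2D("c", [[0, 0]], closed=False)
        with pytest.raises(ValueError, match="duplicate"):
            pj.Contour2D("c", [[0, 0], [0, 0], [1, 1]], closed=True)

    def test_default_anchor_prefers_lamina_edge(self):
        lamina = pj.Contour2D("osseous spiral lamina",
                              [[10, 0], [20, 0], [20, 2], [10, 2]])
        other = circle_contour(r=3.0, center=(0.0, 0.0), label="scala")
        anno = pj.AnnotationSet("s", 1.0, [other, lamina])
        anchor = pj.default_anchor(anno)
        # the lamina edge nearest the overall centroid is its left side
        assert anchor[0] < 15.0
        anno2 = pj.AnnotationSet("s", 1.0, [other])
        anchor2 = pj.default_anchor(anno2)
        assert np.allclose(anchor2, [0.0, 0.0], atol=1e-9)
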