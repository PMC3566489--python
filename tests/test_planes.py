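import numpy as np
import pytest

from planecast import (
    PhantomSpec,
    PlaneSegment,
    Ray,
    Volume,
    choose_axis,
    closed_form,
    face_interpolate,
    generate,
    plane_intersections,
    plane_sample_ray,
    segment_sample,
    trilinear_sample,
)
from planecast.planes import ray_plane_geometry
from planecast.rays import clip_to_volume
from tests.conftest import random_ray_through


def face_bilinear(i0, i1, i3, i6_diag, f1, f2):
    """Bilinear oracle using all four face corners (the formula the
    three-vertex rule deliberately is NOT)."""
    return (
        i0 * (1 - f1) * (1 - f2)
        + i1 * f1 * (1 - f2)
        + i3 * (1 - f1) * f2
        + i6_diag * f1 * f2
    )


class TestChooseAxis:
    @pytest.mark.parametrize(
        "direction, axis",
        [
            ((0, 1, 0), "y"),
            ((0.9, 0.1, 0.1), "x"),
            ((1, 1, 0), "x"),  # tie-break x -> y -> z
            ((0, 1, 1), "y"),
            ((0, 0, -2), "z"),
        ],
    )
    def test_dominant_component_with_tiebreak(self, direction, axis):
        assert choose_axis(direction) == axis

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            choose_axis((0, 0, 0))


class TestPlaneIntersections:
    def test_axis_aligned_ray_hits_each_plane(self, unit_cube):
        ray = Ray(origin=(0.5, -1, 0.5), direction=(0, 1, 0))
        pts = plane_intersections(ray, unit_cube, "y")
        assert [p.t for p in pts] == pytest.approx([1.0, 2.0])
        assert pts[0].point == pytest.approx([0.5, 0.0, 0.5])
        assert pts[1].point == pytest.approx([0.5, 1.0, 0.5])
        assert pts[0].plane_index == 0 and pts[1].plane_index == 1

    def test_grazing_edge_ray(self, unit_cube):
        ray = Ray(origin=(0, -1, 0), direction=(0, 1, 0))
        pts = plane_intersections(ray, unit_cube, "y")
        assert len(pts) == 2
        for p in pts:
            assert p.point[0] == pytest.approx(0.0)
            assert p.point[2] == pytest.approx(0.0)
            assert p.voxel[0] == 0 and p.voxel[2] == 0

    def test_missing_ray_gives_empty_list(self, unit_cube):
        ray = Ray(origin=(5, -1, 0.5), direction=(0, 1, 0))
        assert plane_intersections(ray, unit_cube, "y") == []

    def test_zero_component_axis_is_an_error(self, unit_cube):
        ray = Ray(origin=(0.5, -1, 0.5), direction=(0, 1, 0))
        with pytest.raises(ValueError, match="choose_axis"):
            plane_intersections(ray, unit_cube, "x")

    def test_negative_direction_sorted_by_ray_order(self, affine_volume):
        ray = Ray(origin=(4.0, 10.0, 4.0), direction=(0, -1, 0))
        pts = plane_intersections(ray, affine_volume, "y")
        ts = [p.t for p in pts]
        assert ts == sorted(ts)
        assert pts[0].plane_index == 8  # farthest plane index met first going -y

    def test_intersections_satisfy_plane_and_ray_equations(self, affine_volume, rng):
        """Residuals against both defining equations stay below 1e-9."""
        for _ in range(20):
            ray = random_ray_through(affine_volume, rng)
            axis = choose_axis(ray.direction)
            ax = "xyz".index(axis)
            seg = clip_to_volume(ray, affine_volume)
            for p in plane_intersections(ray, affine_volume, axis):
                plane_coord = p.plane_index * affine_volume.spacing[ax]
                assert abs(p.point[ax] - plane_coord) < 1e-9
                assert np.linalg.norm(p.point - ray.at(p.t)) < 1e-9
                assert seg.t_enter - 1e-9 <= p.t <= seg.t_exit + 1e-9
                # owning voxel consistent with floor rule (upper clamp aside)
                for c in range(3):
                    if c == ax:
                        continue
                    expect = min(
                        int(np.floor(p.point[c] / affine_volume.spacing[c] + 1e-12)),
                        affine_volume.extents[c] - 2,
                    )
                    assert p.voxel[c] == max(expect, 0)


class TestFaceInterpolate:
    def _volume_with_face(self, i0, i1, i3, diag=0.0):
        values = np.zeros((2, 2, 2))
        values[0, 0, 0] = i0
        values[1, 0, 0] = i1  # +x neighbour
        values[0, 0, 1] = i3  # +z neighbour
        values[1, 0, 1] = diag  # diagonal corner (unused by the rule)
        return Volume(values=values, spacing=(1, 1, 1))

    def _point_on_y0(self, vi, vk):
        from planecast.planes import IntersectionPoint

        return IntersectionPoint(
            point=np.array([vi, 0.0, vk]), t=0.0, plane_index=0, voxel=(0, 0, 0)
        )

    def test_identity_at_vertex(self):
        vol = self._volume_with_face(3.5, 4, 8)
        assert face_interpolate(vol, self._point_on_y0(0, 0), "y") == pytest.approx(3.5)

    def test_three_vertex_formula(self):
        vol = self._volume_with_face(0, 4, 8)
        value = face_interpolate(vol, self._point_on_y0(0.5, 0.25), "y")
        assert value == pytest.approx(4.0)

    def test_diagonal_corner_is_ignored(self):
        """The literal three-vertex rule returns 0 at the face centre even
        though the diagonal corner is 1; a bilinear oracle gives 0.25."""
        vol = self._volume_with_face(0, 0, 0, diag=1.0)
        value = face_interpolate(vol, self._point_on_y0(0.5, 0.5), "y")
        assert value == pytest.approx(0.0, abs=1e-12)
        assert face_bilinear(0, 0, 0, 1.0, 0.5, 0.5) == pytest.approx(0.25)

    def test_point_outside_box_rejected(self):
        vol = self._volume_with_face(0, 0, 0)
        with pytest.raises(ValueError, match="outside"):
            face_interpolate(vol, self._point_on_y0(2.5, 0.0), "y")

    def test_face_centre_deviation_is_quarter_cross_term(self):
        """On f = g*xz (the in-plane cross term for a y-cluster) the
        three-vertex rule undershoots the truth by exactly g/4 at face
        centres, while trilinear sampling stays exact."""
        g = 3.2
        spec = PhantomSpec("trilinear", extents=(4, 4, 4), spacing=(1, 1, 1),
                           params={"coeffs": (0, 0, 0, 0, 0, 0, g, 0)})
        vol = generate(spec)
        ray = Ray(origin=(1.5, -1.0, 2.5), direction=(0, 1, 0))
        for p in plane_intersections(ray, vol, "y"):
            truth = closed_form(spec, p.point)
            approx = face_interpolate(vol, p, "y")
            assert truth - approx == pytest.approx(g / 4.0, abs=1e-12)
            assert trilinear_sample(vol, p.point) == pytest.approx(truth, abs=1e-9)


class TestSegmentSample:
    def _segment(self, ie=10.0, iq=20.0, t0=1.0, t1=3.0):
        from planecast.planes import IntersectionPoint

        mk = lambda t, j: IntersectionPoint(
            point=np.zeros(3), t=t, plane_index=j, voxel=(0, 0, 0)
        )
        return PlaneSegment(entry=mk(t0, 0), exit=mk(t1, 1), value_entry=ie, value_exit=iq)

    def test_endpoints_and_midpoint(self):
        seg = self._segment()
        assert segment_sample(1.0, seg) == 10.0
        assert segment_sample(3.0, seg) == 20.0
        assert segment_sample(2.0, seg) == 15.0

    def test_outside_segment_rejected(self):
        with pytest.raises(ValueError):
            segment_sample(0.5, self._segment())

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ZeroDivisionError):
            segment_sample(1.0, self._segment(t0=1.0, t1=1.0))


class TestPlaneSampleRay:
    def test_constant_volume(self, rng):
        vol = Volume(values=np.full((5, 5, 5), 7.5), spacing=(1, 1, 1))
        ray = random_ray_through(vol, rng)
        seg = clip_to_volume(ray, vol)
        positions = np.linspace(seg.t_enter, seg.t_exit, 9)
        np.testing.assert_allclose(plane_sample_ray(vol, ray, positions), 7.5)

    def test_exact_on_affine_fields_along_oblique_rays(self, affine_spec, affine_volume, rng):
        """Within the bracketed intersection span both the face formula and
        the section formula are exact on affine fields, so their
        composition returns the closed form."""
        for _ in range(10):
            ray = random_ray_through(affine_volume, rng)
            axis = choose_axis(ray.direction)
            pts = plane_intersections(ray, affine_volume, axis)
            assert len(pts) >= 2
            positions = np.linspace(pts[0].t, pts[-1].t, 17)
            values = plane_sample_ray(affine_volume, ray, positions)
            expected = [closed_form(affine_spec, ray.at(t)) for t in positions]
            np.testing.assert_allclose(values, expected, rtol=1e-9, atol=1e-9)

    def test_agrees_with_trilinear_on_affine(self, affine_volume, rng):
        for _ in range(10):
            ray = random_ray_through(affine_volume, rng)
            axis = choose_axis(ray.direction)
            pts = plane_intersections(ray, affine_volume, axis)
            positions = np.linspace(pts[0].t, pts[-1].t, 11)
            plane_vals = plane_sample_ray(affine_volume, ray, positions)
            tri_vals = [trilinear_sample(affine_volume, ray.at(t)) for t in positions]
            np.testing.assert_allclose(plane_vals, tri_vals, rtol=1e-9, atol=1e-9)

    def test_position_on_intersection_returns_face_value(self, affine_volume):
        ray = Ray(origin=(2.2, -1.0, 3.1), direction=(0, 1, 0))
        pts = plane_intersections(ray, affine_volume, "y")
        values = plane_sample_ray(affine_volume, ray, [pts[3].t])
        assert values[0] == pytest.approx(
            face_interpolate(affine_volume, pts[3], "y"), abs=1e-12
        )

    def test_values_within_bracketing_face_values(self, rng):
        vol = Volume(values=rng.normal(size=(6, 6, 6)), spacing=(1, 1, 1))
        for _ in range(10):
            ray = random_ray_through(vol, rng)
            axis = choose_axis(ray.direction)
            geom = ray_plane_geometry(ray, vol, axis)
            pts = plane_intersections(ray, vol, axis)
            if len(pts) < 2:
                continue
            from planecast.planes import face_values

            vals = face_values(vol.values, geom)
            positions = np.linspace(pts[0].t, pts[-1].t, 23)
            sampled = plane_sample_ray(vol, ray, positions)
            idx = np.clip(np.searchsorted(geom["t"], positions) - 1, 0, len(vals) - 2)
            lo = np.minimum(vals[idx], vals[idx + 1])
            hi = np.maximum(vals[idx], vals[idx + 1])
            assert np.all(sampled >= lo - 1e-9)
            assert np.all(sampled <= hi + 1e-9)

    def test_positions_outside_span_clamp_to_nearest_intersection(self, affine_volume):
        # Enters through the x=0 side face between two y-planes, so the
        # clipped segment starts with a sliver before the first intersection.
        ray = Ray(origin=(-0.5, -1.0, 3.0), direction=(0.3, 1.0, 0.0))
        seg = clip_to_volume(ray, affine_volume)
        pts = plane_intersections(ray, affine_volume, choose_axis(ray.direction))
        assert seg.t_enter < pts[0].t  # the sliver exists
        sliver_t = (seg.t_enter + pts[0].t) / 2.0
        values = plane_sample_ray(affine_volume, ray, [sliver_t, pts[0].t])
        assert values[0] == pytest.approx(values[1])
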