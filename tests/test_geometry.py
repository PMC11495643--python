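import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from myowork import (
    SEPTAL_SEGMENTS,
    EndocardialSurface,
    assign_aha_segments,
    cavity_volume,
    effective_radius,
    fit_segment_radii,
    patch_areas,
    segment_wall_thickness,
)
from myowork.geometry import GeometryError

from conftest import as_surface, spheroid_surface


def _flat_surface():
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
    tris = np.array([[0, 1, 2], [1, 3, 2]])
    return EndocardialSurface(
        vertices=verts[None], triangles=tris, frame_times=[0.0],
        apex_point=[0, 0, 0], base_centroid=[1, 1, 0])


class TestPatchAreas:
    def test_unit_right_triangle(self, _=None):
        s = _flat_surface()
        assert patch_areas(s, 0)[0] == pytest.approx(0.5)

    def test_icosphere_total_area_matches_analytic(self, icosphere30):
        s = as_surface(icosphere30)
        assert patch_areas(s, 0).sum() == pytest.approx(4 * np.pi * 30**2, rel=0.01)

    def test_rigid_motion_invariance(self, icosphere30, rng):
        s = as_surface(icosphere30)
        a0 = patch_areas(s, 0)
        R = Rotation.random(random_state=7).as_matrix()
        moved = EndocardialSurface(
            vertices=(s.vertices[0] @ R.T + rng.normal(0, 10, 3))[None],
            triangles=s.triangles, frame_times=[0.0],
            apex_point=s.apex_point, base_centroid=s.base_centroid)
        np.testing.assert_allclose(patch_areas(moved, 0), a0, rtol=1e-9)

    def test_degenerate_triangle_zero_area(self):
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]])
        s = EndocardialSurface(vertices=verts[None],
                               triangles=[[0, 1, 2], [0, 1, 3]], frame_times=[0.0],
                               apex_point=[0, 0, 0], base_centroid=[1, 0, 0])
        a = patch_areas(s, 0)
        assert a[0] == 0.0 and a[1] == pytest.approx(0.5)


class TestCavityVolume:
    def test_closed_icosphere(self, icosphere30):
        s = as_surface(icosphere30)
        assert cavity_volume(s, 0) == pytest.approx(4 / 3 * np.pi * 27.0, rel=0.01)

    def test_hemispherical_cup_with_basal_cap(self):
        s = spheroid_surface(a=30, b=30, theta0=np.pi / 2, n_phi=96, n_rings=48)
        assert cavity_volume(s, 0) == pytest.approx(56.55, rel=0.01)

    def test_rigid_motion_invariance(self, icosphere30):
        s = as_surface(icosphere30)
        v0 = cavity_volume(s, 0)
        R = Rotation.from_euler("xyz", [0.3, -1.0, 2.2]).as_matrix()
        moved = EndocardialSurface(
            vertices=(s.vertices[0] @ R.T + 5.0)[None], triangles=s.triangles,
            frame_times=[0.0], apex_point=s.apex_point, base_centroid=s.base_centroid)
        assert cavity_volume(moved, 0) == pytest.approx(v0, rel=1e-9)

    def test_star_convex_volume_against_voxel_oracle(self):
        # smooth star-shaped radius field around a 30 mm sphere
        def radius(theta, phi):
            return 30.0 * (1 + 0.15 * np.sin(3 * phi) * np.sin(theta) ** 2
                           + 0.1 * np.cos(2 * theta))

        n_phi, n_rings = 96, 48
        theta = np.linspace(1e-9, np.pi, n_rings + 1)[:-1]
        phi = np.arange(n_phi) * (2 * np.pi / n_phi)
        th, ph = np.meshgrid(theta, phi, indexing="ij")
        r = radius(th, ph)
        verts = np.column_stack([
            (r * np.sin(th) * np.cos(ph)).ravel(),
            (r * np.sin(th) * np.sin(ph)).ravel(),
            (r * np.cos(th)).ravel()])
        tris = []
        for i in range(n_rings - 1):
            for j in range(n_phi):
                v00, v01 = i * n_phi + j, i * n_phi + (j + 1) % n_phi
                v10, v11 = (i + 1) * n_phi + j, (i + 1) * n_phi + (j + 1) % n_phi
                tris += [(v00, v01, v10), (v01, v11, v10)]
        south = len(verts)
        verts = np.vstack([verts, [0, 0, -radius(np.pi, 0.0)]])
        last = (n_rings - 1) * n_phi
        for j in range(n_phi):
            tris.append((last + j, last + (j + 1) % n_phi, south))
        s = EndocardialSurface(vertices=verts[None], triangles=np.asarray(tris),
                               frame_times=[0.0], apex_point=[0, 0, -30],
                               base_centroid=[0, 0, 30])

        # voxel-count oracle on the analytic region, 0.5 mm grid
        g = np.arange(-38.0, 38.0, 0.5) + 0.25
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        rr = np.sqrt(X**2 + Y**2 + Z**2)
        with np.errstate(invalid="ignore"):
            tt = np.arccos(np.clip(np.where(rr > 0, Z / np.where(rr > 0, rr, 1), 1), -1, 1))
        pp = np.mod(np.arctan2(Y, X), 2 * np.pi)
        inside = rr < radius(tt, pp)
        oracle_ml = inside.sum() * 0.5**3 / 1000.0
        assert cavity_volume(s, 0) == pytest.approx(oracle_ml, rel=0.02)

    def test_two_boundary_loops_rejected(self):
        s = spheroid_surface(n_phi=24, n_rings=12)
        # drop the apex fan -> a second (apical) hole
        tris = s.triangles[: 2 * 24 * 11]
        holed = EndocardialSurface(vertices=s.vertices, triangles=tris,
                                   frame_times=[0.0], apex_point=s.apex_point,
                                   base_centroid=s.base_centroid)
        with pytest.raises(GeometryError, match="boundary loops"):
            cavity_volume(holed, 0)


class TestAHASegments:
    def test_partition_covers_total_area(self, lv_mesh):
        segmap = assign_aha_segments(lv_mesh)
        areas = patch_areas(lv_mesh, 0)
        total = sum(areas[segmap.patch_segment == s].sum() for s in range(1, 18))
        assert total == pytest.approx(areas.sum(), rel=1e-12)
        assert set(np.unique(segmap.patch_segment)) == set(range(1, 18))

    def test_mid_inferoseptal_direction_is_segment_9(self, lv_mesh):
        segmap = assign_aha_segments(lv_mesh)
        cent = lv_mesh.triangle_centroids(0)
        frac = 1.0 - cent[:, 2] / lv_mesh.axis_length
        alpha = np.degrees(np.arctan2(cent[:, 1], cent[:, 0]))
        pick = (np.abs(frac - 0.5) < 0.08) & (np.abs(alpha - 120.0) < 20.0)
        assert pick.any()
        assert np.all(segmap.patch_segment[pick] == 9)

    def test_apex_cap_rule(self, lv_mesh):
        segmap = assign_aha_segments(lv_mesh)
        cent = lv_mesh.triangle_centroids(0)
        frac = 1.0 - cent[:, 2] / lv_mesh.axis_length
        assert np.all(segmap.patch_segment[frac >= 0.97] == 17)

    def test_septal_labels_are_fixed_set(self, lv_mesh):
        segmap = assign_aha_segments(lv_mesh)
        septal = segmap.patch_region == "septum"
        assert set(segmap.patch_segment[septal]) <= SEPTAL_SEGMENTS

    def test_degenerate_axis_rejected(self):
        with pytest.raises(GeometryError, match="degenerate"):
            EndocardialSurface(
                vertices=np.zeros((1, 4, 3)), triangles=[[0, 1, 2]],
                frame_times=[0.0], apex_point=[0, 0, 0], base_centroid=[0, 0, 0])


class TestSegmentRadii:
    def test_sphere_self_consistency(self, rng):
        th = rng.uniform(0.3, np.pi - 0.3, 200)
        ph = rng.uniform(0, 2 * np.pi, 200)
        pts = 25.0 * np.column_stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        r_c, r_l, fb = fit_segment_radii(pts, [0, 0, 1], [0, 0, 0])
        assert r_c == pytest.approx(25.0, abs=0.1)
        assert r_l == pytest.approx(25.0, abs=0.1)

    def test_prolate_equatorial_band(self, rng):
        a, b = 25.0, 50.0
        th = rng.uniform(np.pi / 2 - 0.5, np.pi / 2 + 0.5, 300)
        ph = rng.uniform(0, 2 * np.pi, 300)
        pts = np.column_stack(
            [a * np.sin(th) * np.cos(ph), a * np.sin(th) * np.sin(ph), b * np.cos(th)])
        r_c, r_l, fb = fit_segment_radii(pts, [0, 0, 1], [0, 0, 0])
        assert r_c == pytest.approx(a, abs=0.5)
        # meridional curvature radius near the equator approaches b^2/a
        assert r_l == pytest.approx(b**2 / a, rel=0.15)

    def test_noisy_sphere_recovery(self, rng):
        th = rng.uniform(0.3, np.pi - 0.3, 500)
        ph = rng.uniform(0, 2 * np.pi, 500)
        pts = 25.0 * np.column_stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        pts += rng.normal(0, 0.1, pts.shape)
        r_c, r_l, _ = fit_segment_radii(pts, [0, 0, 1], [0, 0, 0])
        assert r_c == pytest.approx(25.0, rel=0.01)
        assert r_l == pytest.approx(25.0, rel=0.01)

    def test_coplanar_points_fall_back_to_sphere(self):
        th = np.full(40, np.pi / 2)
        ph = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = 25.0 * np.column_stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        r_c, r_l, fb = fit_segment_radii(pts, [0, 0, 1], [0, 0, 0])
        assert fb and r_c == pytest.approx(r_l)

    def test_too_few_points_rejected(self):
        with pytest.raises(GeometryError):
            fit_segment_radii(np.zeros((5, 3)), [0, 0, 1], [0, 0, 0])


class TestEffectiveRadius:
    @pytest.mark.parametrize("rc,rl,expected", [(20, 20, 10), (30, 60, 20)])
    def test_formula(self, rc, rl, expected):
        assert effective_radius(rc, rl) == pytest.approx(expected)

    def test_limit_approaches_r_circ(self):
        vals = [effective_radius(20.0, rl) for rl in (1e2, 1e4, 1e8)]
        assert np.all(np.diff(vals) > 0) and vals[-1] == pytest.approx(20.0, rel=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(GeometryError):
            effective_radius(0.0, 10.0)


class TestWallThickness:
    def test_uniform_passthrough(self):
        h = segment_wall_thickness({s: 10.0 for s in range(1, 18)}, n_frames=4)
        assert h.shape == (17, 4) and np.all(h == 10.0)

    def test_incompressible_scaling(self):
        ratio = np.full((17, 2), 1.0)
        ratio[:, 1] = 0.8
        h = segment_wall_thickness({s: 10.0 for s in range(1, 18)}, 2, ratio)
        assert np.all(h[:, 1] == pytest.approx(12.5))  # area x thickness conserved

    def test_negative_thickness_rejected(self):
        table = {s: 10.0 for s in range(1, 18)}
        table[5] = -1.0
        with pytest.raises(GeometryError):
            segment_wall_thickness(table)

    def test_missing_segment_rejected(self):
        with pytest.raises(GeometryError, match="missing"):
            segment_wall_thickness({1: 10.0})
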