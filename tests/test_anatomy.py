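"""Geometry generator and measurement-apparatus tests."""

import numpy as np
import pytest

from neoaorta import anatomy
from neoaorta.anatomy import (
    Centerline,
    AortaSurface,
    GROUP_MEDIAN_PARAMS,
    PhenotypeParams,
    build_synthetic_aorta,
    define_wall_regions,
    extract_planes,
    measure_arch_angle,
    measure_levels,
    straight_tube,
)


def circular_arc_centerline(radius, depth_needed, n=1200, diameter=1.0):
    """Planar circular arc (apex up) deep enough for the angle construction."""
    drop = min(1.9 * radius, max(1.5 * depth_needed, 1.2 * depth_needed))
    phi_max = np.arccos(np.clip(1.0 - drop / radius, -1.0, 1.0))
    phi = np.linspace(-phi_max, phi_max, n)
    pts = np.column_stack(
        [radius * np.sin(phi), np.zeros_like(phi), radius * np.cos(phi)]
    )
    return Centerline.from_points(pts, diameter)


class TestArchAngle:
    @pytest.mark.parametrize("ratio", [2, 5, 10, 20, 50])
    def test_circular_arc_closed_form(self, ratio):
        """On a circular arc of radius R_c with offset d the angle is
        2*arctan(sqrt(2 R_c d - d^2)/d) by chord geometry."""
        d = 1.0
        r = ratio * d
        cl = circular_arc_centerline(r, d)
        expected = 2.0 * np.degrees(np.arctan(np.sqrt(2 * r * d - d**2) / d))
        measured = measure_arch_angle(cl, d)
        assert abs(measured - expected) < 1.0

    def test_shallow_arc_approaches_straight(self):
        d = 1.0
        angles = [
            measure_arch_angle(circular_arc_centerline(r, d), d)
            for r in (5.0, 10.0, 20.0, 40.0)
        ]
        assert np.all(np.diff(angles) > 0)
        assert angles[-1] > 160.0

    def test_too_short_centerline_errors(self):
        cl = circular_arc_centerline(10.0, 0.5)  # shallow: never drops 3 below apex
        with pytest.raises(ValueError, match="intersect"):
            measure_arch_angle(cl, 3.0)

    def test_ambiguous_maximum_errors(self):
        # two symmetric humps of equal height
        t = np.linspace(0, 4 * np.pi, 400)
        pts = np.column_stack([t, np.zeros_like(t), np.sin(t / 2) ** 2])
        cl = Centerline.from_points(pts, 1.0)
        with pytest.raises(ValueError, match="[Aa]mbiguous"):
            measure_arch_angle(cl, 0.3)

    def test_nonpositive_offset_rejected(self):
        cl = circular_arc_centerline(5.0, 1.0)
        with pytest.raises(ValueError):
            measure_arch_angle(cl, 0.0)


class TestGenerator:
    @pytest.mark.parametrize("group", sorted(GROUP_MEDIAN_PARAMS))
    def test_round_trip_angle_and_levels(self, group, group_geometries):
        """Measured arch angle and level diameters recover the inputs."""
        g = group_geometries[group]
        params, cl, surf = g["params"], g["cl"], g["surf"]
        angle = measure_arch_angle(cl, float(cl.diameter_at(0.5 * cl.length)))
        assert abs(angle - params.arch_angle_deg) < 3.0
        levels = measure_levels(surf, cl)
        targets = {
            "annulus": params.annulus_d,
            "sinus": params.sinus_d,
            "stj": params.stj_d,
            "mid_ascending": params.midAA_d,
        }
        for name, target in targets.items():
            assert levels[name] == pytest.approx(target, rel=0.01)

    def test_determinism(self):
        p = GROUP_MEDIAN_PARAMS["B_mild"]
        cl1, s1 = build_synthetic_aorta(p, seed=11)
        cl2, s2 = build_synthetic_aorta(p, seed=11)
        np.testing.assert_array_equal(s1.vertices, s2.vertices)
        np.testing.assert_array_equal(cl1.points, cl2.points)

    def test_different_seed_perturbs_surface(self):
        p = GROUP_MEDIAN_PARAMS["B_mild"]
        _, s1 = build_synthetic_aorta(p, seed=1)
        _, s2 = build_synthetic_aorta(p, seed=2)
        assert not np.array_equal(s1.vertices, s2.vertices)

    def test_degenerate_equal_diameters_constant_tube(self):
        from scipy.spatial import cKDTree

        p = PhenotypeParams("C_normal", 97.3, 24.0, 24.0, 24.0, 24.0, 0.0)
        cl, surf = build_synthetic_aorta(p, seed=0, jitter=0.0)
        tree = cKDTree(cl.points)
        dist, _ = tree.query(surf.vertices)
        assert np.abs(dist / 1.2 - 1.0).max() < 0.01  # radius 1.2 cm

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeParams("C_normal", 185.0, 22, 30, 26, 24)
        with pytest.raises(ValueError):
            PhenotypeParams("C_normal", 97.3, -1, 30, 26, 24)
        with pytest.raises(ValueError):
            PhenotypeParams("C_normal", 97.3, 22, 30, 26, 24, recirculation_strength=0.5)


class TestPlanes:
    def test_plane_positions_on_straight_tube(self):
        """Plane placement rules verified by arclength arithmetic."""
        lm = {
            "annulus": 1.0, "sinus": 2.0, "stj": 3.0, "mid_ascending": 6.0,
            "brachiocephalic": 12.0, "left_carotid": 14.0, "left_subclavian": 16.0,
        }
        cl, surf = straight_tube(30.0, 2.0, n_points=300, landmarks=lm)
        planes = extract_planes(cl, surf)
        s = [p.arclength for p in planes]
        spacing = cl.length / 299
        expected = [3.0, 10.0, 11.9, 16.1, 20.1]
        assert np.allclose(s, expected, atol=spacing + 1e-9)
        assert np.all(np.diff(s) > 0)
        assert all(np.allclose(np.linalg.norm(p.normal), 1.0) for p in planes)

    def test_plane_ordering_on_generated_geometry(self, group_geometries):
        for g in group_geometries.values():
            s = [p.arclength for p in g["planes"]]
            assert np.all(np.diff(s) > 0)

    def test_missing_landmark_errors(self):
        lm = {"annulus": 1.0, "brachiocephalic": 12.0}
        cl, surf = straight_tube(30.0, 2.0, landmarks=lm)
        with pytest.raises(ValueError, match="left_subclavian"):
            extract_planes(cl, surf)

    def test_out_of_order_landmarks_error(self):
        lm = {"annulus": 13.0, "brachiocephalic": 12.0, "left_subclavian": 16.0}
        cl, surf = straight_tube(30.0, 2.0, landmarks=lm)
        with pytest.raises(ValueError, match="order"):
            extract_planes(cl, surf)


class TestWallRegions:
    def test_cylinder_band_area(self):
        """A +-0.5 d band on a radius-R cylinder has area ~ 2 pi R * 2R."""
        lm = {
            "annulus": 1.0, "sinus": 2.0, "stj": 3.0, "mid_ascending": 6.0,
            "brachiocephalic": 12.0, "left_carotid": 14.0, "left_subclavian": 16.0,
        }
        cl, surf = straight_tube(30.0, 2.0, n_points=600, n_theta=64, landmarks=lm)
        planes = extract_planes(cl, surf)
        regions = {r.label: r for r in define_wall_regions(surf, cl, planes)}
        areas = surf.triangle_areas()
        R = 1.0
        for label in ("proximal_AA", "arch", "descending"):
            band = float(areas[regions[label].triangle_ids].sum())
            assert band == pytest.approx(2 * np.pi * R * 2 * R, rel=0.05)

    def test_regions_disjoint_and_nonempty(self, group_geometries):
        for g in group_geometries.values():
            ids = [r.triangle_ids for r in g["regions"]]
            allids = np.concatenate(ids)
            assert len(allids) == len(set(allids.tolist()))
            assert all(len(i) > 0 for i in ids)

    def test_overlapping_bands_stay_disjoint(self):
        # planes closer than one diameter: tie-break to the nearest plane
        lm = {
            "annulus": 1.0, "sinus": 2.0, "stj": 3.0, "mid_ascending": 6.0,
            "brachiocephalic": 12.0, "left_carotid": 12.8, "left_subclavian": 13.5,
        }
        cl, surf = straight_tube(30.0, 2.0, n_points=300, landmarks=lm)
        planes = extract_planes(cl, surf)
        regions = define_wall_regions(surf, cl, planes)
        allids = np.concatenate([r.triangle_ids for r in regions])
        assert len(allids) == len(set(allids.tolist()))

    def test_empty_region_errors(self):
        lm = {
            "annulus": 1.0, "sinus": 2.0, "stj": 3.0, "mid_ascending": 6.0,
            # plane4 would land beyond the tube end
            "brachiocephalic": 12.0, "left_carotid": 14.0, "left_subclavian": 16.0,
        }
        cl, surf = straight_tube(30.0, 2.0, n_points=300, landmarks=lm)
        planes = extract_planes(cl, surf)
        # restrict the surface to the first 5 cm so distal bands are empty
        keep = np.where(surf.triangle_centroids()[:, 2] < 5.0)[0]
        small = AortaSurface(surf.vertices, surf.triangles[keep], surf.landmarks)
        with pytest.raises(ValueError, match="empty"):
            define_wall_regions(small, cl, planes)


class TestLevels:
    def test_circular_tube_levels(self):
        lm = {"annulus": 3.0, "sinus": 6.0, "stj": 9.0, "mid_ascending": 12.0}
        cl, surf = straight_tube(20.0, 2.4, n_points=300, n_theta=96, landmarks=lm)
        levels = measure_levels(surf, cl)
        for v in levels.values():
            assert v == pytest.approx(24.0, rel=0.005)

    def test_elliptical_midAA_caliper_mean(self):
        """Ellipse semi-axes 10 / 14.4 mm: caliper mean (20+28.8)/2 mm."""
        z = np.linspace(0.0, 10.0, 120)
        a, b = 1.0, 1.44  # cm
        theta = np.linspace(0, 2 * np.pi, 192, endpoint=False)
        rings = [
            np.column_stack([a * np.cos(theta), b * np.sin(theta), np.full_like(theta, zi)])
            for zi in z
        ]
        verts = np.concatenate(rings)
        ntheta = len(theta)
        faces = []
        for i in range(len(z) - 1):
            for j in range(ntheta):
                p, q = i * ntheta + j, i * ntheta + (j + 1) % ntheta
                r, s = (i + 1) * ntheta + j, (i + 1) * ntheta + (j + 1) % ntheta
                faces.extend([(p, q, s), (p, s, r)])
        cl = Centerline.from_points(
            np.column_stack([np.zeros_like(z), np.zeros_like(z), z]), 2 * b
        )
        lm = {"annulus": 2.0, "sinus": 4.0, "stj": 6.0, "mid_ascending": 5.0}
        surf = AortaSurface(verts, np.array(faces), lm)
        levels = measure_levels(surf, cl)
        assert levels["mid_ascending"] == pytest.approx(24.4, rel=0.01)
        # equivalent-circle diameter at the other levels: 2*sqrt(ab)
        assert levels["stj"] == pytest.approx(2 * np.sqrt(a * b) * 10, rel=0.01)

    def test_missing_landmark_errors(self):
        cl, surf = straight_tube(20.0, 2.4, landmarks={"annulus": 3.0})
        with pytest.raises(ValueError, match="landmark"):
            measure_levels(surf, cl)


class TestCenterlineInvariants:
    def test_validation(self):
        pts = np.column_stack([np.zeros(60), np.zeros(60), np.linspace(0, 10, 60)])
        with pytest.raises(ValueError, match="positive"):
            Centerline.from_points(pts, -1.0)
        with pytest.raises(ValueError, match="50"):
            Centerline.from_points(pts[:10], 1.0)
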