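"""Centerline extraction, integral length, contours and circle fitting."""

import numpy as np
import pytest

from bametrics.grids import VoxelGrid, LandmarkSet, LANDMARK_NAMES
from bametrics.phantoms import TubePhantomSpec, make_tube_phantom
from bametrics.vessel import (CenterlinePath, DisconnectedVesselError,
                              GeometryConfig, LandmarkError,
                              UnreliableDiameterError, branch_geometry,
                              cross_section_contour, extract_centerline,
                              fit_circle, integral_length)


# ---------------------------------------------------------------------------
# circle fit
# ---------------------------------------------------------------------------

class TestFitCircle:
    def test_exact_on_noiseless_circle(self):
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = np.stack([1.0 + 2 * np.cos(ang), -0.5 + 2 * np.sin(ang)], axis=1)
        center, radius, rms = fit_circle(pts)
        assert radius == pytest.approx(2.0, abs=1e-9)
        assert np.allclose(center, [1.0, -0.5], atol=1e-9)
        assert rms == pytest.approx(0.0, abs=1e-9)

    def test_right_triangle_circumcircle(self):
        # right angle at origin: circumcircle diameter = hypotenuse
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        _, radius, _ = fit_circle(pts)
        assert radius == pytest.approx(2.5, abs=1e-9)

    def test_noisy_circle_radius_monte_carlo(self):
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(1000):
            ang = rng.uniform(0, 2 * np.pi, 16)
            pts = np.stack([2 * np.cos(ang), 2 * np.sin(ang)], axis=1)
            pts += rng.normal(0, 0.05, pts.shape)
            _, radius, _ = fit_circle(pts)
            errs.append(radius - 2.0)
        assert abs(np.mean(errs)) < 0.05

    def test_collinear_points_rejected(self):
        pts = np.stack([np.arange(5.0), 2 * np.arange(5.0)], axis=1)
        with pytest.raises(ValueError, match="collinear"):
            fit_circle(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_circle(np.array([[0.0, 0.0], [1.0, 1.0]]))


# ---------------------------------------------------------------------------
# integral length on synthetic paths
# ---------------------------------------------------------------------------

def _two_point_path():
    pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 50.0]])
    return CenterlinePath(pts, np.array([0.0, 50.0]),
                          {"BA_apex": 0, "PICA_origin": 1})


class TestIntegralLength:
    def test_two_point_path(self):
        assert integral_length(_two_point_path(), "BA_apex",
                               "PICA_origin") == pytest.approx(50.0)

    def test_symmetry_and_degenerate(self):
        p = _two_point_path()
        assert integral_length(p, "PICA_origin", "BA_apex") == \
            integral_length(p, "BA_apex", "PICA_origin")
        assert integral_length(p, "BA_apex", "BA_apex") == 0.0

    def test_unattached_landmark_errors(self):
        with pytest.raises(LandmarkError, match="VA_fusion"):
            integral_length(_two_point_path(), "BA_apex", "VA_fusion")


# ---------------------------------------------------------------------------
# centerline extraction on phantoms
# ---------------------------------------------------------------------------

class TestExtractCenterline:
    def test_straight_tube_length_close_to_euclidean(self, straight_tube):
        _, vol, lms, truth = straight_tube
        path = extract_centerline(vol, lms)
        L = integral_length(path, "BA_apex", "PICA_origin")
        euclid = np.linalg.norm(lms["PICA_origin"] - lms["BA_apex"])
        assert L == pytest.approx(euclid, rel=0.01)
        assert L >= euclid - 1e-6  # integral length bounds the chord

    def test_helix_length_matches_closed_form(self, helix_tube):
        _, vol, lms, truth = helix_tube
        path = extract_centerline(vol, lms)
        L = integral_length(path, "BA_apex", "PICA_origin")
        assert L == pytest.approx(truth.branch_length_mm, rel=0.015)

    def test_landmarks_attach_in_order_within_tolerance(self, helix_tube):
        _, vol, lms, truth = helix_tube
        path = extract_centerline(vol, lms)
        idx = [path.landmark_indices[n] for n in LANDMARK_NAMES]
        assert idx == sorted(idx)
        diag = np.linalg.norm(vol.spacing)
        for n in LANDMARK_NAMES:
            d = np.linalg.norm(path.points[path.landmark_indices[n]] - lms[n])
            assert d <= diag

    def test_gap_in_tube_raises_disconnected(self, straight_tube):
        _, vol, lms, _ = straight_tube
        vals = vol.values.copy()
        kmid = vals.shape[2] // 2
        vals[:, :, kmid - 2:kmid + 2] = 0.0
        with pytest.raises(DisconnectedVesselError, match="disconnected"):
            extract_centerline(VoxelGrid(vals, vol.affine), lms)

    def test_landmark_in_background_raises(self, straight_tube):
        _, vol, lms, _ = straight_tube
        pts = lms.to_json_dict()
        corner = vol.voxel_to_world(np.array([2.0, 2.0, 2.0]))
        pts["AICA_origin"] = list(corner)
        with pytest.raises(LandmarkError, match="AICA_origin"):
            extract_centerline(vol, LandmarkSet.from_json_dict(pts))

    def test_axis_permutation_invariance(self, helix_tube):
        _, vol, lms, truth = helix_tube
        path = extract_centerline(vol, lms)
        L0 = integral_length(path, "BA_apex", "PICA_origin")
        perm = (2, 0, 1)
        vals = np.transpose(vol.values, perm)
        aff = vol.affine.copy()
        aff[:3, :3] = vol.affine[:3, perm]
        vol2 = VoxelGrid(vals, aff)
        path2 = extract_centerline(vol2, lms)
        L1 = integral_length(path2, "BA_apex", "PICA_origin")
        assert L1 == pytest.approx(L0, rel=0.001)

    def test_resample_step_halving_changes_length_little(self, helix_tube):
        _, vol, lms, _ = helix_tube
        L = {}
        for step in (0.5, 0.25):
            cfg = GeometryConfig(resample_step_mm=step)
            path = extract_centerline(vol, lms, cfg)
            L[step] = integral_length(path, "BA_apex", "PICA_origin")
        assert L[0.25] == pytest.approx(L[0.5], rel=0.005)


# ---------------------------------------------------------------------------
# cross-sections and branch geometry
# ---------------------------------------------------------------------------

class TestContoursAndBranch:
    def test_constant_tube_mid_branch_diameter(self, straight_tube):
        _, vol, lms, _ = straight_tube
        path = extract_centerline(vol, lms)
        c = cross_section_contour(vol, path, path.total_length / 2)
        assert c.valid
        assert c.diameter_mm == pytest.approx(3.0, abs=0.15)

    def test_out_of_fov_contour_flagged_not_raised(self, straight_tube):
        _, vol, lms, _ = straight_tube
        path = extract_centerline(vol, lms)
        cropped = VoxelGrid(vol.values[:, :, :60], vol.affine)
        zmax = cropped.voxel_to_world(np.array([0, 0, 59.0]))[2]
        s = path.arclength[-1] - (path.points[-1][2] - zmax) + 1.0
        c = cross_section_contour(cropped, path, min(s, path.total_length))
        assert not c.valid
        assert "coverage" in c.reason

    def test_arclength_outside_path_raises(self, straight_tube):
        _, vol, lms, _ = straight_tube
        path = extract_centerline(vol, lms)
        with pytest.raises(ValueError, match="outside"):
            cross_section_contour(vol, path, path.total_length + 10)

    def test_tapered_tube_diameters_increase(self):
        spec = TubePhantomSpec(centerline_kind="straight", length_mm=50,
                               radius_mm=(1.2, 1.8), seed=4)
        vol, lms, truth = make_tube_phantom(spec)
        path = extract_centerline(vol, lms)
        svals = np.linspace(5, path.total_length - 5, 15)
        diams = [cross_section_contour(vol, path, s).diameter_mm for s in svals]
        # monotone within noise: compare smoothed ends
        assert np.mean(diams[-5:]) - np.mean(diams[:5]) > 0.3
        fit = np.polyfit(svals, diams, 1)
        assert fit[0] > 0

    def test_constant_tube_branch_geometry(self, straight_tube):
        _, vol, lms, _ = straight_tube
        path = extract_centerline(vol, lms)
        geo = branch_geometry(vol, path)
        assert geo.landmark_pair == ("BA_apex", "PICA_origin")
        assert geo.actual_length_mm == pytest.approx(50.0, abs=0.75)
        assert geo.median_diameter_mm == pytest.approx(3.0, abs=0.15)
        assert geo.n_rejected <= 0.1 * geo.n_contours

    def test_tapered_median_is_mid_arclength_value(self):
        spec = TubePhantomSpec(centerline_kind="straight", length_mm=50,
                               radius_mm=(1.2, 1.8), seed=5)
        vol, lms, truth = make_tube_phantom(spec)
        path = extract_centerline(vol, lms)
        geo = branch_geometry(vol, path)
        smid = 0.5 * (truth.landmark_arclengths_mm[0]
                      + truth.landmark_arclengths_mm[-1])
        assert geo.median_diameter_mm == pytest.approx(
            truth.diameter_at_arclength(smid), abs=0.15)

    def test_median_diameter_invariant_to_affine_intensity_rescale(
            self, straight_tube):
        _, vol, lms, _ = straight_tube
        g1 = branch_geometry(vol, extract_centerline(vol, lms))
        vol2 = VoxelGrid(vol.values * 3.7 + 120.0, vol.affine)
        g2 = branch_geometry(vol2, extract_centerline(vol2, lms))
        assert g2.median_diameter_mm == pytest.approx(g1.median_diameter_mm,
                                                      abs=1e-6)

    def test_unreliable_diameter_error_carries_partial_result(
            self, straight_tube):
        _, vol, lms, _ = straight_tube
        path = extract_centerline(vol, lms)
        cfg = GeometryConfig(max_residual_mm=1e-6)  # reject every contour
        with pytest.raises(UnreliableDiameterError) as ei:
            branch_geometry(vol, path, config=cfg)
        partial = ei.value.partial
        assert partial.actual_length_mm == pytest.approx(50.0, abs=0.75)
        assert partial.n_rejected > 0.5 * (partial.n_contours
                                           + partial.n_rejected)
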