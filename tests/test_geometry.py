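import warnings

import numpy as np
import pytest

import beamgait as bg
from beamgait.geometry import (PhysicalScale, apply_physical_scale,
                               derive_camera_pair, estimate_fundamental,
                               merge_90, metric_upgrade, reconstruct_45,
                               triangulate, _fundamental_from_pair,
                               _sampson_sq)
from beamgait.pose import PoseSequence
from beamgait.pose_io import CalibrationLineSet
from beamgait.simulate import StereoRigSpec, project_stereo

SCALE = PhysicalScale(beam_length_cm=60.0, incline_deg=0.0)


def _norm_h(x):
    return np.column_stack([x, np.ones(len(x))])


class TestFundamental:
    def test_exact_correspondences_recover_f(self, stereo_45):
        xL, xR = stereo_45.lines.correspondences()
        F = estimate_fundamental(xL, xR)
        Ftrue = _fundamental_from_pair(stereo_45.P_left, stereo_45.P_right)
        d = min(np.linalg.norm(F - Ftrue), np.linalg.norm(F + Ftrue))
        assert d < 1e-9
        res = _sampson_sq(F, _norm_h(xL), _norm_h(xR))
        assert np.median(res) < 1e-8

    def test_seven_correspondences_rejected(self, stereo_45):
        xL, xR = stereo_45.lines.correspondences()
        with pytest.raises(ValueError, match="at least 8"):
            estimate_fundamental(xL[:7], xR[:7])

    def test_gross_outlier_excluded(self, stereo_45):
        """One wildly wrong correspondence leaves the estimate unchanged
        within tolerance (least-median robustness)."""
        xL, xR = stereo_45.lines.correspondences()
        # augment with projected feature points for a richer inlier set
        fl = stereo_45.pose_left.coords[0]
        fr = stereo_45.pose_right.coords[0]
        xL = np.concatenate([xL, fl])
        xR = np.concatenate([xR, fr])
        clean = estimate_fundamental(xL, xR, seed=1)
        xL_bad = np.concatenate([xL, [[15.0, 700.0]]])
        xR_bad = np.concatenate([xR, [[1200.0, 20.0]]])
        robust = estimate_fundamental(xL_bad, xR_bad, seed=1)
        d = min(np.linalg.norm(robust - clean),
                np.linalg.norm(robust + clean))
        assert d < 1e-6


class TestCameraPair:
    def test_round_trip_f(self, stereo_45):
        xL, xR = stereo_45.lines.correspondences()
        F = estimate_fundamental(xL, xR)
        P_L, P_R = derive_camera_pair(F)
        F2 = _fundamental_from_pair(P_L, P_R)
        d = min(np.linalg.norm(F2 - F), np.linalg.norm(F2 + F))
        assert d < 1e-9

    def test_left_camera_is_canonical(self, stereo_45):
        xL, xR = stereo_45.lines.correspondences()
        F = estimate_fundamental(xL, xR)
        P_L, _ = derive_camera_pair(F)
        assert np.array_equal(P_L, np.hstack([np.eye(3), np.zeros((3, 1))]))

    def test_full_rank_f_rejected(self):
        with pytest.raises(ValueError, match="rank 2"):
            derive_camera_pair(np.eye(3))


class TestTriangulate:
    def test_round_trip_with_true_cameras(self, clean_gait, stereo_45):
        _, pose, _ = clean_gait
        pts, res = triangulate(stereo_45.P_left, stereo_45.P_right,
                               stereo_45.pose_left.coords[0],
                               stereo_45.pose_right.coords[0])
        assert np.allclose(pts, pose.coords[0], atol=1e-8)
        assert res.max() < 1e-8

    def test_swapped_views_flagged_by_residual(self, stereo_45):
        _, res = triangulate(stereo_45.P_left, stereo_45.P_right,
                             stereo_45.pose_right.coords[0],
                             stereo_45.pose_left.coords[0])
        assert res.max() > 10.0

    def test_point_at_infinity_rejected(self):
        P_L = np.hstack([np.eye(3), np.zeros((3, 1))])
        P_R = np.hstack([np.eye(3), [[-1.0], [0.0], [0.0]]])
        # zero disparity along the baseline: depth is infinite
        with pytest.raises(ValueError, match="infinity"):
            triangulate(P_L, P_R, [[0.0, 0.0]], [[0.0, 0.0]])

    def test_opposed_cameras_trigger_ill_conditioning_warning(self,
                                                              stereo_90):
        with pytest.warns(UserWarning, match="ill-conditioned"):
            triangulate(stereo_90.P_left, stereo_90.P_right,
                        stereo_90.pose_left.coords.reshape(-1, 2),
                        stereo_90.pose_right.coords.reshape(-1, 2))

    def test_45_degree_cameras_do_not_warn(self, stereo_45):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            triangulate(stereo_45.P_left, stereo_45.P_right,
                        stereo_45.pose_left.coords.reshape(-1, 2),
                        stereo_45.pose_right.coords.reshape(-1, 2))


class TestMetricUpgrade:
    def test_noiseless_orthogonality(self, stereo_45):
        xL, xR = stereo_45.lines.correspondences()
        F = estimate_fundamental(xL, xR)
        P_L, P_R = derive_camera_pair(F)
        model = metric_upgrade(P_L, P_R, stereo_45.lines)
        assert model.orthogonality_residual < 1e-8
        assert model.reprojection_rms < 1e-8
        # the simulated rig's intrinsics are recovered
        assert np.allclose(np.diag(model.K), [900, 900, 1], atol=1e-4)

    def test_prealigned_scene_gives_identity_upgrade(self):
        """When the true left camera is already canonical and the scene is
        axis-aligned, H reduces to the identity up to scale."""
        rng = np.random.default_rng(0)
        R = np.eye(3)
        P_L = np.hstack([R, np.zeros((3, 1))])
        c = np.array([2.0, 0.5, -1.0])
        th = np.deg2rad(35)
        Ry = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                       [-np.sin(th), 0, np.cos(th)]])
        P_R = np.hstack([Ry, (-Ry @ c)[:, None]])
        lines3d = {
            "beam": np.array([[[-2, -1, 8.0], [2, -1, 8]],
                              [[-2, -1.4, 8.2], [2, -1.4, 8.2]]]),
            "box_y": np.array([[[2.5, -1, 8.0], [2.5, 1, 8]],
                               [[3.0, -1, 9.0], [3.0, 1, 9]]]),
            "box_z": np.array([[[2.5, -1, 8.5], [2.5, -1, 10]],
                               [[2.5, 1, 8.5], [2.5, 1, 10]]]),
        }

        def proj(P, pts):
            h = np.column_stack([pts, np.ones(len(pts))])
            q = (P @ h.T).T
            return q[:, :2] / q[:, 2:3]

        views = {}
        for name, P in (("left", P_L), ("right", P_R)):
            views[name] = {lab: proj(P, seg.reshape(-1, 3)).reshape(2, 2, 2)
                           for lab, seg in lines3d.items()}
        lines = CalibrationLineSet(views=views)
        model = metric_upgrade(P_L, P_R, lines)
        H = model.H / model.H[3, 3]
        # identity up to a similarity fixing the gauge: direction part
        # must be a scaled identity
        A = H[:3, :3]
        s = np.trace(A) / 3
        assert np.allclose(A, s * np.eye(3), atol=1e-6 * abs(s))

    def test_coincident_direction_pairs_rejected(self, stereo_45):
        views = {v: {k: a.copy() for k, a in segs.items()}
                 for v, segs in stereo_45.lines.views.items()}
        # replace the box_y pair with a translated copy of the beam pair:
        # two pairs share one direction
        for v in views:
            views[v]["box_y"] = views[v]["beam"] + 7.0
        lines = CalibrationLineSet(views=views)
        xL, xR = lines.correspondences()
        F = estimate_fundamental(xL, xR)
        P_L, P_R = derive_camera_pair(F)
        with pytest.raises(ValueError):
            metric_upgrade(P_L, P_R, lines)


class TestPhysicalScale:
    def test_beam_length_recovered(self, clean_gait, stereo_45):
        """The reconstructed beam measures exactly the physical length."""
        _, pose, _ = clean_gait
        rec, model = reconstruct_45(stereo_45.pose_left,
                                    stereo_45.pose_right,
                                    stereo_45.lines, SCALE)
        # the true beam runs from (0,0,0) to (60,0,0); feature points are
        # recovered on that scale
        assert np.abs(rec.coords - pose.coords).max() < 1e-6

    def test_zero_incline_shear_is_identity(self):
        pts = np.random.default_rng(0).normal(size=(20, 3))
        beam = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        out, T = apply_physical_scale(pts, PhysicalScale(60.0, 0.0), beam)
        assert np.allclose(out, (pts - beam[0]) * 30.0)

    def test_doubling_beam_length_doubles_coordinates(self):
        pts = np.random.default_rng(1).normal(size=(20, 3))
        beam = np.array([[0.1, 0.2, 0.3], [1.1, 0.2, 0.3]])
        out1, _ = apply_physical_scale(pts, PhysicalScale(60.0, 5.0), beam)
        out2, _ = apply_physical_scale(pts, PhysicalScale(120.0, 5.0), beam)
        assert np.allclose(out2, 2 * out1)

    def test_zero_length_beam_rejected(self):
        beam = np.zeros((2, 3))
        with pytest.raises(ValueError, match="zero length"):
            apply_physical_scale(np.zeros((1, 3)), SCALE, beam)


class TestReconstruct45:
    def test_noiseless_round_trip(self, clean_gait, stereo_45):
        _, pose, _ = clean_gait
        rec, _ = reconstruct_45(stereo_45.pose_left, stereo_45.pose_right,
                                stereo_45.lines, SCALE)
        rms = np.sqrt(np.mean((rec.coords - pose.coords) ** 2))
        assert rms < 0.01 * SCALE.beam_length_cm
        assert rec.units == "cm" and rec.dims == 3

    def test_noisy_round_trip(self, clean_gait):
        _, pose, _ = clean_gait
        proj = project_stereo(pose, StereoRigSpec(), pixel_noise_sd=0.5,
                              seed=13)
        rec, _ = reconstruct_45(proj.pose_left, proj.pose_right, proj.lines,
                                SCALE, seed=13,
                                augment_correspondences=True)
        rms = np.sqrt(np.mean((rec.coords - pose.coords) ** 2))
        assert rms < 0.02 * SCALE.beam_length_cm

    def test_mismatched_frame_counts_rejected(self, stereo_45):
        from dataclasses import replace
        short = replace(stereo_45.pose_right,
                        coords=stereo_45.pose_right.coords[:-5])
        with pytest.raises(ValueError, match="frame counts differ"):
            reconstruct_45(stereo_45.pose_left, short, stereo_45.lines,
                           SCALE)

    def test_invariant_to_image_similarity_transforms(self, clean_gait,
                                                      stereo_45):
        """Rotating/scaling/translating each view's pixel coordinates
        consistently leaves the reconstruction unchanged."""
        _, pose, _ = clean_gait

        def sim2d(pts, angle, scale, shift):
            c, s = np.cos(angle), np.sin(angle)
            R = np.array([[c, -s], [s, c]])
            return scale * pts @ R.T + shift

        a, sc, sh = 0.15, 1.3, np.array([40.0, -25.0])
        views = {}
        posed = {}
        for v, p in (("left", stereo_45.pose_left),
                     ("right", stereo_45.pose_right)):
            views[v] = {lab: sim2d(arr.reshape(-1, 2), a, sc,
                                   sh).reshape(2, 2, 2)
                        for lab, arr in stereo_45.lines.views[v].items()}
            posed[v] = PoseSequence(coords=sim2d(
                p.coords.reshape(-1, 2), a, sc, sh).reshape(p.coords.shape),
                fps=p.fps, units="px", config=p.config)
        rec, _ = reconstruct_45(posed["left"], posed["right"],
                                CalibrationLineSet(views=views), SCALE)
        assert np.abs(rec.coords - pose.coords).max() < 1e-6


class TestMerge90:
    def _flat_view(self, coords2d):
        """A synthetic 90-degree 'view': beam along pixel x at y=400."""
        lines = {
            "beam": np.array([[[100.0, 400.0], [700.0, 400.0]],
                              [[100.0, 420.0], [700.0, 420.0]]]),
            "box_y": np.array([[[720.0, 390.0], [760.0, 390.0]],
                               [[720.0, 430.0], [760.0, 430.0]]]),
            "box_z": np.array([[[720.0, 300.0], [720.0, 380.0]],
                               [[760.0, 300.0], [760.0, 380.0]]]),
        }
        return lines

    def test_mirrored_copy_recovers_original(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(150, 650, size=(8, 18, 2))
        coords[..., 1] = rng.uniform(300, 400, size=(8, 18))
        linesL = self._flat_view(coords)
        # mirror about the beam midline y=410
        coordsR = coords.copy()
        coordsR[..., 1] = 2 * 410.0 - coords[..., 1]
        linesR = {k: v.copy() for k, v in linesL.items()}
        for k in linesR:
            linesR[k][..., 1] = 2 * 410.0 - linesR[k][..., 1]
        lines = CalibrationLineSet(views={"left": linesL, "right": linesR})
        poseL = PoseSequence(coords=coords, fps=30)
        poseR = PoseSequence(coords=coordsR, fps=30)
        merged = merge_90(poseL, poseR, lines, SCALE, mirror="y")
        # compare against the aligned left view alone
        alone = merge_90(poseL, poseL.copy(), lines_same_view(linesL),
                         SCALE, mirror=None)
        assert np.allclose(merged.coords, alone.coords, atol=1e-9)

    def test_symmetric_displacements_cancel(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(150, 650, size=(8, 18, 2))
        d = rng.normal(scale=3.0, size=base.shape)
        linesL = self._flat_view(base)
        lines = CalibrationLineSet(views={"left": linesL,
                                          "right": {k: v.copy()
                                                    for k, v in
                                                    linesL.items()}})
        merged = merge_90(PoseSequence(coords=base + d, fps=30),
                          PoseSequence(coords=base - d, fps=30),
                          lines, SCALE, mirror=None)
        truth = merge_90(PoseSequence(coords=base, fps=30),
                         PoseSequence(coords=base.copy(), fps=30),
                         lines, SCALE, mirror=None)
        assert np.allclose(merged.coords, truth.coords, atol=1e-9)

    def test_missing_mirror_warns_on_opposed_views(self, stereo_90):
        with pytest.warns(UserWarning, match="anti-correlated"):
            merge_90(stereo_90.pose_left, stereo_90.pose_right,
                     stereo_90.lines, SCALE, mirror=None)

    def test_opposed_views_merge_consistently(self, clean_gait, stereo_90):
        """The merged 2D posture tracks the true beam-plane coordinates."""
        _, pose, _ = clean_gait
        merged = merge_90(stereo_90.pose_left, stereo_90.pose_right,
                          stereo_90.lines, SCALE, mirror="y")
        x_err = merged.coords[:, :, 0] - pose.coords[:, :, 0]
        assert np.abs(x_err).max() < 0.5  # residual perspective distortion
        # vertical coordinate correlates with the true z
        c = np.corrcoef(merged.coords[:, :, 1].ravel(),
                        pose.coords[:, :, 2].ravel())[0, 1]
        assert c > 0.999


def lines_same_view(view_lines):
    return CalibrationLineSet(views={
        "left": {k: v.copy() for k, v in view_lines.items()},
        "right": {k: v.copy() for k, v in view_lines.items()}})
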