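"""Synthetic fly model, kinematic sequences, ensembles and rendering."""

import numpy as np
import pytest

from flyhull import synthetic_fly as sf
from flyhull.conventions import wing_vectors


class TestFlyModel:
    def test_default_model_contract(self, model):
        """Watertight body, planar simple wings, positive area."""
        assert model.body_mesh().is_watertight
        assert model.wing_area > 0
        # outline is planar by construction (2D) and simple: shapely check
        from shapely.geometry import Polygon

        assert Polygon(model.wing_outline).is_valid

    def test_wing_scaling_about_hinge(self):
        """Doubling the wing length scales the outline by two."""
        m1 = sf.build_fly_model(wing_length=2.5e-3)
        m2 = sf.build_fly_model(wing_length=5.0e-3)
        assert np.allclose(m2.wing_outline[:, 1], 2.0 * m1.wing_outline[:, 1])
        assert m2.wing_area == pytest.approx(2.0 * m1.wing_area, rel=1e-9)

    def test_area_matches_shoelace_oracle(self, model):
        """Stored wing area equals an independent shoelace evaluation."""
        poly = model.wing_outline
        x, y = poly[:, 0], poly[:, 1]
        shoelace = 0.5 * abs(
            np.sum(x * np.roll(y, -1)) - np.sum(y * np.roll(x, -1))
        )
        assert model.wing_area == pytest.approx(shoelace, rel=1e-12)

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ValueError):
            sf.build_fly_model(body_length=-1e-3)


class TestPoseModel:
    def test_identity_pose(self, model):
        body = sf.BodyPose.from_angles((0, 0, 0))
        posed = sf.pose_model(model, body, sf.WingPose(90, 0, 0, +1),
                              sf.WingPose(90, 0, 0, -1))
        assert np.allclose(posed.body_center, 0)
        assert np.allclose(posed.body_rotation[:, 0], [1, 0, 0])

    def test_span_follows_rotation_oracle(self, model):
        """The posed span equals the convention rotation applied to the
        rest span (independent composition)."""
        body = sf.BodyPose.from_angles((0, 0, 0), yaw_deg=30, pitch_deg=20)
        wp = sf.WingPose(115.0, -8.0, 55.0, -1)
        posed = sf.pose_model(model, body, sf.WingPose(90, 0, 0, +1), wp)
        s_expect, c_expect = wing_vectors(
            wp.phi, wp.theta, wp.psi, wp.side, body.x_b, body.y_b
        )
        assert np.allclose(posed.wings[-1].span, s_expect, atol=1e-12)
        assert np.allclose(posed.wings[-1].chord, c_expect, atol=1e-12)

    def test_ground_truth_vectors_orthonormal(self, model):
        body = sf.BodyPose.from_angles((0, 0, 0), pitch_deg=45)
        posed = sf.pose_model(model, body, sf.WingPose(70, 12, 120, +1),
                              sf.WingPose(70, 12, 120, -1))
        for w in posed.wings.values():
            assert abs(np.linalg.norm(w.span) - 1) < 1e-9
            assert abs(np.linalg.norm(w.chord) - 1) < 1e-9
            assert abs(np.dot(w.span, w.chord)) < 1e-9

    def test_bad_rotation_rejected(self, model):
        with pytest.raises(ValueError):
            sf.BodyPose(np.zeros(3), np.eye(3) * 1.1)


class TestSequences:
    def test_default_frames_per_wingbeat(self, model):
        seq = sf.generate_wingbeat_sequence(model, n_wingbeats=1)
        assert len(seq) == 73
        assert seq.frames_per_wingbeat == 73

    def test_zero_amplitude_is_constant(self, model):
        spec = sf.WingbeatSpec(amp_phi=0.0, amp_theta=0.0, amp_psi=0.0)
        seq = sf.generate_wingbeat_sequence(model, wing_spec=spec,
                                            n_wingbeats=1)
        phis = {p.phi for p in seq.left}
        assert phis == {spec.mean_phi}

    def test_phi_extrema_match_request(self, model):
        """The analytic waveform attains the requested front/back angles."""
        spec = sf.WingbeatSpec(mean_phi=90.0, amp_phi=70.0)
        seq = sf.generate_wingbeat_sequence(model, wing_spec=spec,
                                            n_wingbeats=2)
        phis = np.array([p.phi for p in seq.left])
        assert phis.max() == pytest.approx(160.0, abs=1e-9)
        assert phis.min() == pytest.approx(20.0, abs=0.2)  # sampling grid

    def test_bad_wingbeat_count(self, model):
        with pytest.raises(ValueError):
            sf.generate_wingbeat_sequence(model, n_wingbeats=0)


class TestEnsemble:
    def test_empty_and_determinism(self):
        assert sf.sample_pose_ensemble(n=0, seed=1) == []
        a = sf.sample_pose_ensemble(n=5, seed=42)
        b = sf.sample_pose_ensemble(n=5, seed=42)
        for (ba, la, ra), (bb, lb, rb) in zip(a, b):
            assert np.allclose(ba.rotation, bb.rotation)
            assert (la.phi, la.theta, la.psi) == (lb.phi, lb.theta, lb.psi)

    def test_samples_within_requested_support(self):
        ens = sf.sample_pose_ensemble({"phi": (10.0, 20.0)}, n=200, seed=3)
        phis = [w.phi for _, wl, wr in ens for w in (wl, wr)]
        assert min(phis) >= 10.0 and max(phis) <= 20.0

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            sf.sample_pose_ensemble({"phi": (30.0, 10.0)}, n=1)


class TestRendering:
    def test_body_silhouette_matches_analytic_ellipse(self, model):
        """A level body seen from the vertical camera projects an ellipse
        whose pixel area matches the analytic value within 2%."""
        from flyhull.cameras import make_rig

        rig = make_rig("hybrid4", pixel_pitch=30e-6)
        top = rig[3]
        body = sf.BodyPose.from_angles((0, 0, 0))  # level: top view is a
        posed = sf.pose_model(model, body, sf.WingPose(90, 0, 0, +1),
                              sf.WingPose(90, 0, 0, -1))
        view = sf._render_camera(posed, top)
        a, b = model.body_semi_axes[0], model.body_semi_axes[1]
        analytic = np.pi * a * b / (30e-6) ** 2
        assert view.body_mask.sum() == pytest.approx(analytic, rel=0.02)

    def test_constructed_occlusion(self, model):
        """A wing pointing straight away from a camera sits behind the
        body in that view (occluded) while a perpendicular camera sees it."""
        from flyhull.cameras import make_rig

        rig = make_rig("cartesian3", pixel_pitch=30e-6)
        body = sf.BodyPose.from_angles((0, 0, 0))
        # phi=90, theta=0: spans along +/- y.  The right wing (-y) points
        # away from camera 2 (placed on +y, looking along -y), so its
        # foreshortened projection lies behind the nearer body.
        posed = sf.pose_model(model, body, sf.WingPose(90, 0, 0, +1),
                              sf.WingPose(90, 0, 0, -1))
        views = sf.render_silhouettes(posed, rig)
        from_y = views[2]
        from_x = views[1]
        occl_frac = from_y.visible_wing_mask(-1).sum() / max(
            1, from_y.wing_masks[-1].sum())
        open_frac = from_x.visible_wing_mask(-1).sum() / max(
            1, from_x.wing_masks[-1].sum())
        assert occl_frac < 0.5
        assert open_frac > 0.9

    def test_resolution_scaling(self, model):
        """Doubling the image resolution quadruples silhouette pixel area."""
        from flyhull.cameras import make_rig

        body = sf.BodyPose.from_angles((0, 0, 0), pitch_deg=45)
        left, right = sf.WingPose(90, 0, 45, +1), sf.WingPose(90, 0, 45, -1)
        posed = sf.pose_model(model, body, left, right)
        r1 = make_rig("hybrid4", image_size=(128, 128), pixel_pitch=60e-6)
        r2 = make_rig("hybrid4", image_size=(256, 256), pixel_pitch=30e-6)
        a1 = sf.render_silhouettes(posed, r1)[1].full.sum()
        a2 = sf.render_silhouettes(posed, r2)[1].full.sum()
        assert a2 == pytest.approx(4 * a1, rel=0.05)

    def test_deterministic_and_masks_tile(self, rendered_frame):
        """Rendering is reproducible; part masks cover the silhouette."""
        posed, views, _, _ = rendered_frame
        from flyhull.cameras import make_rig

        again = sf.render_silhouettes(
            posed, make_rig("hybrid4", pixel_pitch=30e-6))
        for cid, view in views.items():
            assert np.array_equal(view.full, again[cid].full)
            union = (view.body_mask | view.wing_masks[+1]
                     | view.wing_masks[-1])
            assert np.array_equal(view.full, union)
            # winner labels only where something is hit
            assert np.array_equal(view.labels > 0, view.full)

    def test_twisted_wing_renders(self):
        """A twisted wing poses and renders without degenerate facets."""
        from flyhull.cameras import make_rig

        m = sf.build_fly_model(twist_deg=20.0)
        body = sf.BodyPose.from_angles((0, 0, 0), pitch_deg=45)
        posed = sf.pose_model(m, body, sf.WingPose(90, 0, 45, +1),
                              sf.WingPose(90, 0, 45, -1))
        assert len(posed.wings[+1].facets) > 1
        views = sf.render_silhouettes(posed,
                                      make_rig("hybrid4", pixel_pitch=30e-6))
        assert views[1].wing_masks[+1].sum() > 100
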