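"""Body axes, rates, stroke plane and wingbeat summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from flyhull import kinematics as kin
from flyhull import conventions as cv
from flyhull.synthetic_fly import generate_wingbeat_sequence


class TestStrokePlane:
    def test_normal_relations(self):
        r = cv.body_rotation(33.0, 21.0, -12.0)
        sp = kin.stroke_plane(r[:, 0], r[:, 1], origin=np.array([1, 2, 3.0]))
        assert abs(np.dot(sp.normal, r[:, 1])) < 1e-12
        ang = np.degrees(np.arccos(np.clip(np.dot(sp.normal, r[:, 0]), -1, 1)))
        assert ang == pytest.approx(45.0, abs=1e-9)


class TestEstimateYb:
    @staticmethod
    def _truth_series(n_wingbeats=4, **body_kw):
        from flyhull.synthetic_fly import BodyTrajectorySpec, build_fly_model

        model = build_fly_model()
        seq = generate_wingbeat_sequence(
            model, body_spec=BodyTrajectorySpec(**body_kw),
            n_wingbeats=n_wingbeats,
        )
        t_n = len(seq)
        xb = np.array([b.x_b for b in seq.body])
        yb = np.array([b.y_b for b in seq.body])
        s_l = np.empty((t_n, 3))
        s_r = np.empty((t_n, 3))
        for i in range(t_n):
            s_l[i], _ = cv.wing_vectors(seq.left[i].phi, seq.left[i].theta,
                                        seq.left[i].psi, +1, xb[i], yb[i])
            s_r[i], _ = cv.wing_vectors(seq.right[i].phi, seq.right[i].theta,
                                        seq.right[i].psi, -1, xb[i], yb[i])
        return seq.times, xb, yb, s_l, s_r

    def test_exact_for_zero_roll(self):
        """With exact spans and no body roll, y_b is recovered to <2 deg
        at every frame."""
        times, xb, yb, s_l, s_r = self._truth_series()
        est = kin.estimate_yb(times, xb, s_l, s_r)
        err = np.degrees(np.arccos(np.clip(
            np.einsum("ij,ij->i", est, yb), -1, 1)))
        assert err.max() < 2.0

    def test_orthonormal_output(self):
        times, xb, yb, s_l, s_r = self._truth_series()
        est = kin.estimate_yb(times, xb, s_l, s_r)
        assert np.allclose(np.einsum("ij,ij->i", est, xb), 0, atol=1e-9)
        assert np.allclose(np.linalg.norm(est, axis=1), 1, atol=1e-9)
        z = np.cross(xb, est)
        assert np.allclose(np.linalg.norm(z, axis=1), 1, atol=1e-9)

    def test_mirror_symmetric_construction(self):
        """For perfectly mirrored perpendicular spans the sample equals
        the normalized half-difference exactly."""
        times = np.arange(300, dtype=float)
        xb = np.tile([1.0, 0, 0], (300, 1))
        y_true = np.array([0.0, 1.0, 0.0])
        # spans oscillating in the y-z plane, mirrored
        th = 0.4 * np.sin(2 * np.pi * times / 73.0)
        s_l = np.column_stack([0.2 * np.cos(2 * np.pi * times / 73.0),
                               np.cos(th), np.sin(th)])
        s_l /= np.linalg.norm(s_l, axis=1, keepdims=True)
        s_r = s_l * np.array([1.0, -1.0, 1.0])
        est = kin.estimate_yb(times, xb, s_l, s_r)
        err = np.degrees(np.arccos(np.clip(est @ y_true, -1, 1)))
        assert err.max() < 1.0


class TestBodyRates:
    def test_constant_rotation_about_x(self):
        """100 deg/s about x_b gives p=100, q=r=0 within 1 deg/s."""
        dt = 1e-3
        times = np.arange(300) * dt
        r0 = cv.body_rotation(10.0, 40.0, -5.0)
        rots = np.array([
            r0 @ Rotation.from_rotvec([np.deg2rad(100.0) * t, 0, 0]).as_matrix()
            for t in times
        ])
        df = kin.body_angles_and_rates(times, rots)
        mid = df.iloc[50:250]
        assert np.allclose(mid["p"], 100.0, atol=1.0)
        assert np.allclose(mid[["q", "r"]], 0.0, atol=1.0)

    def test_static_body_zero_rates(self):
        times = np.arange(10) * 1e-3
        rots = np.tile(cv.body_rotation(5, 5, 5), (10, 1, 1))
        df = kin.body_angles_and_rates(times, rots)
        assert np.allclose(df[["p", "q", "r"]], 0.0, atol=1e-9)

    def test_rate_error_shrinks_quadratically(self):
        """Central differences on a time-varying rate converge at second
        order: halving dt cuts the error by about four."""
        amp, om = np.deg2rad(30.0), 2 * np.pi * 50.0

        def max_err(dt):
            times = np.arange(int(0.02 / dt) + 40) * dt
            rots = np.array([
                Rotation.from_rotvec([amp * np.sin(om * t), 0, 0]).as_matrix()
                for t in times
            ])
            df = kin.body_angles_and_rates(times, rots)
            p_true = np.rad2deg(amp * om * np.cos(om * times))
            return np.abs(df["p"].to_numpy()[5:-5] - p_true[5:-5]).max()

        e1, e2 = max_err(2e-4), max_err(1e-4)
        assert e2 < 0.5 * e1

    def test_yoll_axis_tilt(self):
        """r = -p/3 tilts the rotation axis 18.4 deg below the body axis."""
        tilt = kin.rotation_axis_tilt_deg(300.0, -100.0)
        assert tilt == pytest.approx(np.degrees(np.arctan(1.0 / 3.0)),
                                     abs=1e-9)
        assert tilt == pytest.approx(18.43, abs=0.01)

    def test_nonorthonormal_axes_warn_and_fix(self):
        times = np.arange(5) * 1e-3
        rots = np.tile(np.eye(3) * 1.001, (5, 1, 1))
        with pytest.warns(UserWarning, match="re-orthogonaliz"):
            df = kin.body_angles_and_rates(times, rots)
        assert np.allclose(df[["yaw", "pitch", "roll"]], 0.0, atol=1e-6)


class TestWingbeatSummaries:
    def test_harmonic_front_back_angles(self, model):
        """Amplitude 70 about mean 90: front 160, back 20 per wing."""
        seq = generate_wingbeat_sequence(model, n_wingbeats=5)
        t_n = len(seq)
        tab = pd.DataFrame({
            "phi_L": [seq.left[i].phi for i in range(t_n)],
            "phi_R": [seq.right[i].phi for i in range(t_n)],
        })
        out = kin.wingbeat_summaries(tab)
        assert len(out) == 4  # 5 minima delimit 4 complete beats
        for s in out:
            assert s.phi_front_left == pytest.approx(160.0, abs=0.5)
            assert s.phi_back_left == pytest.approx(20.0, abs=0.5)
            assert s.front_stroke_asymmetry == pytest.approx(0.0, abs=1e-9)
            assert s.phi_front_left >= s.phi_back_left

    def test_too_short_returns_empty(self):
        tab = pd.DataFrame({"phi_L": [90.0, 91.0, 92.0],
                            "phi_R": [90.0, 91.0, 92.0]})
        assert kin.wingbeat_summaries(tab) == []
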