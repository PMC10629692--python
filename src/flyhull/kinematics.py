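"""Body axes, stroke plane, wing Euler angles and body rates.

Assembles per-frame geometric estimates (body axis, wing span/chord
vectors) into the standard 12-DOF representation: body position, body
yaw/pitch/roll, and three Euler angles per wing measured with respect to
the stroke plane (fixed at 45 deg below the body long axis; see
:mod:`flyhull.conventions`).

The body lateral axis ``y_b`` cannot be read off the nearly cylindrically
symmetric body hull; it is estimated once per back-stroke from the wing
span vectors at the instants they are most perpendicular to ``x_b``, then
interpolated to all frames (monotone cubic) and re-orthogonalized.

Body angular velocity is expressed in the body frame as (p, q, r) — the
components about (x_b, y_b, z_b) — computed by central differences of the
body rotation matrix; angular accelerations by a further central
difference; both can be averaged per wingbeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import argrelextrema
from scipy.spatial.transform import Rotation

from .conventions import (
    body_angles_from_rotation,
    chord_reference_frame,
    stroke_plane_frame,
    stroke_plane_normal,
    unit,
)
from .conventions import wing_euler_angles as _wing_euler_angles


@dataclass
class StrokePlane:
    """Stroke plane: unit normal and a point (the body CM) on the plane."""

    normal: np.ndarray
    origin: np.ndarray


def stroke_plane(x_b: np.ndarray, y_b: np.ndarray,
                 origin: np.ndarray | None = None) -> StrokePlane:
    """Stroke plane with normal = x_b rotated by -45 deg about y_b."""
    n = stroke_plane_normal(x_b, y_b)
    o = np.zeros(3) if origin is None else np.asarray(origin, float)
    return StrokePlane(normal=n, origin=o)


def wing_euler_angles(
    s: np.ndarray, c: np.ndarray, side: int,
    x_b: np.ndarray, y_b: np.ndarray,
) -> tuple[float, float, float]:
    """(phi, theta, psi) of a wing from its span and chord unit vectors.

    Thin wrapper over the convention-defining implementation; raises
    ``ValueError`` at gimbal poses (span parallel to the stroke-plane
    normal) — callers hold the previous frame's phi there.
    """
    return _wing_euler_angles(s, c, side, x_b, y_b)


# ---------------------------------------------------------------------------
# y_b estimation
# ---------------------------------------------------------------------------

def estimate_yb(
    times: np.ndarray,
    x_b: np.ndarray,
    s_left: np.ndarray,
    s_right: np.ndarray,
    return_info: bool = False,
    valid: np.ndarray | None = None,
):
    """Per-frame body lateral axis from the wing span vectors.

    For every back-stroke (descending arc of the mean forward span
    component) the instant at which each wing's span is most perpendicular
    to ``x_b`` is located; the lateral axis sample is the mirror average
    ``(s_L - s_R) / 2`` projected perpendicular to ``x_b``.  Samples are
    interpolated to all frames with a monotone cubic and re-orthogonalized
    against ``x_b`` per frame.

    Parameters are (T,)-time and (T, 3) unit-vector arrays; NaN span rows
    are ignored and ``valid`` (a (T,) bool mask) optionally bars frames
    from contributing sample values (e.g. frames with suspect wing
    hulls), without affecting the stroke-phase signal.  Returns the
    (T, 3) ``y_b`` series; with ``return_info=True`` also a dict with the
    sample times (outside their range ``y_b`` is held constant — the
    lateral axis, and hence body roll, is structurally unresolved there).
    """
    times = np.asarray(times, float)
    x_b = np.asarray(x_b, float)
    s_l = np.asarray(s_left, float).copy()
    s_r = np.asarray(s_right, float).copy()
    t_n = len(times)
    # stroke-phase signal from the raw spans (before any validity mask:
    # barred frames cluster near stroke reversal, exactly where the
    # signal's extrema live)
    fwd = 0.5 * (
        np.einsum("ij,ij->i", s_l, x_b) + np.einsum("ij,ij->i", s_r, x_b)
    )
    fwd = np.where(np.isfinite(fwd), fwd, 0.0)
    if valid is not None:
        bad = ~np.asarray(valid, bool)
        s_l[bad] = np.nan
        s_r[bad] = np.nan
    # back-strokes: descending arcs between a local max and the next local
    # min of the forward span component; extremum detection scaled to the
    # dominant stroke period so estimation noise cannot fake extra strokes
    from .segmentation import dominant_period

    try:
        period = dominant_period(fwd, min_period=6)
    except ValueError:
        period = max(8, t_n // 2)
    order = max(2, period // 6)
    maxima = argrelextrema(fwd, np.greater_equal, order=order)[0]
    minima = argrelextrema(fwd, np.less_equal, order=order)[0]
    # deduplicate plateaus
    maxima = maxima[np.insert(np.diff(maxima) > order, 0, True)]
    minima = minima[np.insert(np.diff(minima) > order, 0, True)]
    windows = []
    for m in maxima:
        later = minima[minima > m + 1]
        if later.size:
            windows.append((m, later[0]))
    sample_t, sample_y = [], []
    for a, b in windows:
        seg = slice(a, b + 1)

        def best(s_arr):
            dots = np.abs(np.einsum("ij,ij->i", s_arr[seg], x_b[seg]))
            dots = np.where(np.isfinite(dots), dots, np.inf)
            return a + int(np.argmin(dots))

        i_l, i_r = best(s_l), best(s_r)
        if not (np.all(np.isfinite(s_l[i_l])) and np.all(np.isfinite(s_r[i_r]))):
            continue
        i_mid = (i_l + i_r) // 2
        # average over a small window around the sampling instants to damp
        # single-frame span noise
        win_l = slice(max(0, i_l - 2), min(t_n, i_l + 3))
        win_r = slice(max(0, i_r - 2), min(t_n, i_r + 3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            y = 0.5 * (np.nanmean(s_l[win_l], axis=0)
                       - np.nanmean(s_r[win_r], axis=0))
        y = y - float(y @ x_b[i_mid]) * x_b[i_mid]
        if not np.all(np.isfinite(y)) or np.linalg.norm(y) < 1e-9:
            continue
        sample_t.append(times[i_mid])
        sample_y.append(unit(y))
    if not sample_t:
        raise ValueError("no usable back-stroke found for y_b estimation")
    # adjacent windows can land samples on the same frame: average them
    uniq_t, inv = np.unique(np.asarray(sample_t), return_inverse=True)
    if len(uniq_t) < len(sample_t):
        merged = [unit(np.mean([sample_y[j] for j in np.flatnonzero(inv == i)],
                               axis=0)) for i in range(len(uniq_t))]
        sample_t, sample_y = list(uniq_t), merged
    if len(sample_t) == 1:
        warnings.warn("single y_b sample: low-confidence lateral axis")
        y_all = np.tile(sample_y[0], (t_n, 1))
    else:
        st = np.asarray(sample_t)
        sy = np.asarray(sample_y)
        interp = PchipInterpolator(st, sy, axis=0, extrapolate=False)
        y_all = interp(times)
        # hold the end samples outside the sampled range (cubic
        # extrapolation of sparse samples diverges)
        y_all[times < st[0]] = sy[0]
        y_all[times > st[-1]] = sy[-1]
    # per-frame Gram-Schmidt against x_b
    dots = np.einsum("ij,ij->i", y_all, x_b)
    y_all = y_all - dots[:, None] * x_b
    norms = np.linalg.norm(y_all, axis=1, keepdims=True)
    y_all = y_all / norms
    if return_info:
        return y_all, {"sample_times": np.asarray(sample_t)}
    return y_all


# ---------------------------------------------------------------------------
# body angles and rates
# ---------------------------------------------------------------------------

def orthonormalize(r: np.ndarray) -> np.ndarray:
    """Nearest proper rotation matrix (SVD projection)."""
    u, _, vt = np.linalg.svd(r)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt

def body_angles_and_rates(
    times: np.ndarray, rotations: np.ndarray
) -> pd.DataFrame:
    """Yaw/pitch/roll, body-frame angular velocity (p, q, r) and its
    derivative from a series of body rotation matrices.

    ``rotations`` is (T, 3, 3) with columns = body axes in the lab frame.
    Angular velocity uses the rotation-vector central difference
    ``log(R_{k+1} R_{k-1}^T) / (2 dt)`` expressed in the body frame;
    endpoint frames use one-sided differences.  Angles are deg, rates
    deg/s, accelerations deg/s^2.
    """
    times = np.asarray(times, float)
    rot = np.asarray(rotations, float)
    t_n = len(times)
    if t_n < 3:
        raise ValueError("need at least three frames for rates")
    for k in range(t_n):
        if not np.allclose(rot[k] @ rot[k].T, np.eye(3), atol=1e-8):
            warnings.warn("non-orthonormal body axes: re-orthogonalizing")
            rot[k] = orthonormalize(rot[k])
    ypr = np.array([body_angles_from_rotation(r) for r in rot])
    omega_body = np.empty((t_n, 3))
    for k in range(t_n):
        k0, k1 = max(0, k - 1), min(t_n - 1, k + 1)
        dt = times[k1] - times[k0]
        rv = Rotation.from_matrix(rot[k1] @ rot[k0].T).as_rotvec()
        omega_lab = rv / dt
        omega_body[k] = rot[k].T @ omega_lab
    omega_body = np.rad2deg(omega_body)
    acc = np.gradient(omega_body, times, axis=0)
    return pd.DataFrame(
        {
            "t": times,
            "yaw": ypr[:, 0],
            "pitch": ypr[:, 1],
            "roll": ypr[:, 2],
            "p": omega_body[:, 0],
            "q": omega_body[:, 1],
            "r": omega_body[:, 2],
            "pdot": acc[:, 0],
            "qdot": acc[:, 1],
            "rdot": acc[:, 2],
        }
    )


def rotation_axis_tilt_deg(p: float, r: float) -> float:
    """Tilt of the effective body rotation axis below x_b, in degrees.

    For a coordinated turn combining yaw and roll with ``r = -p/3`` the
    axis is tilted down by ``atan(1/3) ~ 18.4 deg`` (the "yoll" axis).
    """
    return float(np.rad2deg(np.arctan2(-r, p)))


# ---------------------------------------------------------------------------
# wingbeat segmentation and summaries
# ---------------------------------------------------------------------------

@dataclass
class WingbeatSummary:
    """Per-wingbeat stroke extremes and wingbeat-averaged body dynamics."""

    index: int
    frame_range: tuple[int, int]
    phi_front_left: float
    phi_front_right: float
    phi_back_left: float
    phi_back_right: float
    mean_front: float
    mean_pdot: float
    mean_qdot: float
    mean_rdot: float

    @property
    def front_stroke_asymmetry(self) -> float:
        """phi_f,L - phi_f,R: the roll-control stroke asymmetry."""
        return self.phi_front_left - self.phi_front_right


def wingbeat_bounds(
    phi_mean: np.ndarray, nominal_period: float | None = None
) -> list[tuple[int, int]]:
    """Delimit wingbeats at the back-stroke extrema (local minima) of the
    mean stroke angle, with a minimum separation of half the nominal
    period (estimated from the dominant oscillation when not given)."""
    phi_mean = np.asarray(phi_mean, float)
    n = len(phi_mean)
    if nominal_period is None:
        from .segmentation import dominant_period

        try:
            nominal_period = float(dominant_period(phi_mean, min_period=4))
        except ValueError:
            return []  # too short (or constant): no complete wingbeat
    min_sep = max(2, int(nominal_period // 2))
    minima = argrelextrema(phi_mean, np.less_equal, order=min_sep)[0]
    minima = minima[np.insert(np.diff(minima) > min_sep, 0, True)]
    return [(int(a), int(b)) for a, b in zip(minima[:-1], minima[1:])]


def wingbeat_summaries(table: pd.DataFrame) -> list[WingbeatSummary]:
    """Per-wingbeat front/back stroke angles and averaged accelerations.

    ``table`` is a kinematics table with columns ``phi_L, phi_R`` and
    (optionally) ``pdot, qdot, rdot``.  Returns one summary per complete
    wingbeat; empty when fewer than one complete beat is present.
    """
    phi_l = table["phi_L"].to_numpy()
    phi_r = table["phi_R"].to_numpy()
    bounds = wingbeat_bounds(0.5 * (phi_l + phi_r))
    out = []
    for i, (a, b) in enumerate(bounds):
        seg = slice(a, b + 1)

        def col_mean(name):
            return float(table[name].iloc[seg].mean()) if name in table else np.nan

        fl, fr = float(np.nanmax(phi_l[seg])), float(np.nanmax(phi_r[seg]))
        out.append(
            WingbeatSummary(
                index=i,
                frame_range=(a, b),
                phi_front_left=fl,
                phi_front_right=fr,
                phi_back_left=float(np.nanmin(phi_l[seg])),
                phi_back_right=float(np.nanmin(phi_r[seg])),
                mean_front=0.5 * (fl + fr),
                mean_pdot=col_mean("pdot"),
                mean_qdot=col_mean("qdot"),
                mean_rdot=col_mean("rdot"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def assemble_kinematics(
    times: np.ndarray,
    positions: np.ndarray,
    x_b: np.ndarray,
    spans: dict[int, np.ndarray],
    chords: dict[int, np.ndarray],
    psi_locals: dict[int, list[list[tuple[float, np.ndarray, float]]]] | None = None,
    flags: list[set[str]] | None = None,
    y_b: np.ndarray | None = None,
) -> pd.DataFrame:
    """Build the per-frame kinematics table from geometric series.

    ``spans``/``chords`` map side (+1/-1) to (T, 3) unit-vector arrays.
    Computes ``y_b``/``z_b`` via :func:`estimate_yb` (unless a
    precomputed ``y_b`` series is given), the wing Euler angles per frame
    (holding phi through gimbal poses), body angles and rates, and
    attaches local pitch angles ``psi_k`` when provided.
    """
    times = np.asarray(times, float)
    t_n = len(times)
    x_b = np.asarray(x_b, float)
    if y_b is None:
        y_b = estimate_yb(times, x_b, spans[+1], spans[-1])
    z_b = np.cross(x_b, y_b)
    rotations = np.stack([x_b, y_b, z_b], axis=-1)
    body = body_angles_and_rates(times, rotations)
    body["x"] = positions[:, 0]
    body["y"] = positions[:, 1]
    body["z"] = positions[:, 2]

    ang = {f"{name}_{s}": np.full(t_n, np.nan)
           for name in ("phi", "theta", "psi") for s in ("L", "R")}
    frame_flags = [set() for _ in range(t_n)] if flags is None else flags
    for side, tag in ((+1, "L"), (-1, "R")):
        s_arr, c_arr = spans[side], chords[side]
        last_phi = np.nan
        for k in range(t_n):
            if not (np.all(np.isfinite(s_arr[k])) and np.all(np.isfinite(c_arr[k]))):
                frame_flags[k].add(f"wing_{tag}_missing")
                continue
            try:
                phi, th, psi = wing_euler_angles(
                    s_arr[k], c_arr[k], side, x_b[k], y_b[k]
                )
            except ValueError:
                frame_flags[k].add(f"gimbal_{tag}")
                phi = last_phi
                th = 90.0 * np.sign(float(s_arr[k] @ z_b[k]))
                psi = np.nan
            ang[f"phi_{tag}"][k] = phi
            ang[f"theta_{tag}"][k] = th
            ang[f"psi_{tag}"][k] = psi
            last_phi = phi
    for col, v in ang.items():
        body[col] = v
    if psi_locals:
        n_sec = max(
            (len(fr) for frames in psi_locals.values() for fr in frames),
            default=0,
        )
        for side, tag in ((+1, "L"), (-1, "R")):
            frames = psi_locals.get(side, [])
            for k_sec in range(n_sec):
                col = np.full(t_n, np.nan)
                for k, chords_k in enumerate(frames):
                    if k_sec < len(chords_k):
                        col[k] = chords_k[k_sec][2]
                body[f"psi{k_sec + 1}_{tag}"] = col
    body["flags"] = ["|".join(sorted(f)) for f in frame_flags]
    return body
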