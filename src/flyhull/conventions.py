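"""Geometric conventions shared across the package.

Frames
------
* Lab frame: right-handed, ``z`` up (gravity along ``-z``).
* Body frame: ``x_b`` forward (tail to head), ``y_b`` left, ``z_b`` up;
  right-handed and orthonormal, ``z_b = x_b x y_b``.
* Image frame: origin at the top-left pixel, ``x`` right, ``y`` down.

Stroke plane
------------
The stroke-plane normal ``n_sp`` is obtained by rotating ``x_b`` by -45 deg
about ``y_b``; the stroke plane passes through the body centre of mass.  The
in-plane "forward" direction is ``f_sp = y_b x n_sp`` and the wing stroke
angle phi is measured within the plane from body-backward (``-f_sp``) toward
the front, so the front stroke is the maximum of phi.

Wing Euler angles
-----------------
For a wing on side ``sigma`` (+1 left, -1 right) with span unit vector ``s``
and chord unit vector ``c`` (trailing edge toward leading edge):

* ``theta``: elevation of ``s`` above the stroke plane,
  ``theta = asin(s . n_sp)``;
* ``phi``: azimuth of the in-plane projection of ``s``, measured from
  body-backward toward the side's lateral axis ``sigma * y_b`` and beyond,
  so ``phi = 90 deg`` is the wing pointing straight sideways;
* ``psi``: rotation of ``c`` about ``s``; ``psi = 0`` when the chord lies in
  the stroke plane pointing forward, ``psi = 90 deg`` when the wing plane is
  perpendicular to the stroke plane with the leading edge up.

Left/right conventions are mirror symmetric: mirroring a pose through the
body x-z plane leaves (phi, theta, psi) unchanged.
"""

from __future__ import annotations

import numpy as np

STROKE_PLANE_TILT_DEG = 45.0  # stroke plane fixed 45 deg below the body axis


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize the last axis of ``v`` to unit length."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize a zero vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about an arbitrary unit axis."""
    a = unit(axis)
    t = np.deg2rad(angle_deg)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0.0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def body_rotation(yaw_deg: float, pitch_deg: float, roll_deg: float) -> np.ndarray:
    """Body orientation matrix from Z-Y'-X'' (yaw, pitch, roll) angles.

    Columns are the body axes (x_b, y_b, z_b) expressed in the lab frame.
    Positive pitch raises the nose (x_b tilts toward lab +z).
    """
    cz, sz = np.cos(np.deg2rad(yaw_deg)), np.sin(np.deg2rad(yaw_deg))
    cy, sy = np.cos(np.deg2rad(pitch_deg)), np.sin(np.deg2rad(pitch_deg))
    cx, sx = np.cos(np.deg2rad(roll_deg)), np.sin(np.deg2rad(roll_deg))
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
    # positive pitch tilts the nose toward lab +z
    ry = np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return rz @ ry @ rx


def body_angles_from_rotation(r: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`body_rotation`; returns (yaw, pitch, roll) in deg."""
    pitch = np.rad2deg(np.arcsin(np.clip(r[2, 0], -1.0, 1.0)))
    yaw = np.rad2deg(np.arctan2(r[1, 0], r[0, 0]))
    roll = np.rad2deg(np.arctan2(r[2, 1], r[2, 2]))
    return float(yaw), float(pitch), float(roll)


def stroke_plane_normal(x_b: np.ndarray, y_b: np.ndarray) -> np.ndarray:
    """Unit normal of the stroke plane: x_b rotated by -45 deg about y_b."""
    return rotation_about_axis(y_b, -STROKE_PLANE_TILT_DEG) @ unit(x_b)


def stroke_plane_frame(
    x_b: np.ndarray, y_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (n_sp, f_sp, b_sp): plane normal, in-plane forward, backward."""
    n_sp = stroke_plane_normal(x_b, y_b)
    f_sp = unit(np.cross(unit(y_b), n_sp))
    return n_sp, f_sp, -f_sp


def _chord_frame(
    s: np.ndarray, n_sp: np.ndarray, side: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reference chord direction (psi=0) and its quadrature for span ``s``.

    ``c0`` lies in the stroke plane, perpendicular to ``s``, pointing toward
    the fly's front; ``w`` completes the right-handed-per-side triad so that
    psi=+90 pitches the leading edge above the stroke plane.
    """
    c0 = np.cross(n_sp, unit(s))
    nrm = np.linalg.norm(c0)
    if nrm < 1e-12:
        raise ValueError("span parallel to stroke-plane normal (gimbal pose)")
    c0 = -side * c0 / nrm
    w = side * np.cross(unit(s), c0)
    return c0, w


def chord_reference_frame(
    s: np.ndarray, n_sp: np.ndarray, side: int
) -> tuple[np.ndarray, np.ndarray]:
    """Public alias of the psi reference frame for span ``s``: returns
    ``(c0, w)`` with ``psi = atan2(c . w, c . c0)`` for a chord ``c``."""
    return _chord_frame(np.asarray(s, float), np.asarray(n_sp, float), side)


def wing_vectors(
    phi_deg: float,
    theta_deg: float,
    psi_deg: float,
    side: int,
    x_b: np.ndarray = (1.0, 0.0, 0.0),
    y_b: np.ndarray = (0.0, 1.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Forward map: wing Euler angles -> (span, chord) unit vectors, lab frame.

    ``side`` is +1 for the left wing, -1 for the right wing.
    """
    if side not in (+1, -1):
        raise ValueError("side must be +1 (left) or -1 (right)")
    x_b = unit(np.asarray(x_b, float))
    y_b = unit(np.asarray(y_b, float))
    n_sp, _f_sp, b_sp = stroke_plane_frame(x_b, y_b)
    lat = side * y_b
    phi = np.deg2rad(phi_deg)
    th = np.deg2rad(theta_deg)
    in_plane = np.cos(phi) * b_sp + np.sin(phi) * lat
    s = np.cos(th) * in_plane + np.sin(th) * n_sp
    c0, w = _chord_frame(s, n_sp, side)
    psi = np.deg2rad(psi_deg)
    c = np.cos(psi) * c0 + np.sin(psi) * w
    return s, c


def wing_euler_angles(
    s: np.ndarray,
    c: np.ndarray,
    side: int,
    x_b: np.ndarray = (1.0, 0.0, 0.0),
    y_b: np.ndarray = (0.0, 1.0, 0.0),
) -> tuple[float, float, float]:
    """Inverse map: (span, chord) unit vectors -> (phi, theta, psi) in deg.

    Raises ``ValueError`` for gimbal poses (span parallel to the stroke-plane
    normal), where phi is undefined.
    """
    if side not in (+1, -1):
        raise ValueError("side must be +1 (left) or -1 (right)")
    s = unit(np.asarray(s, float))
    c = unit(np.asarray(c, float))
    x_b = unit(np.asarray(x_b, float))
    y_b = unit(np.asarray(y_b, float))
    n_sp, _f_sp, b_sp = stroke_plane_frame(x_b, y_b)
    lat = side * y_b
    sn = float(np.clip(np.dot(s, n_sp), -1.0, 1.0))
    theta = np.rad2deg(np.arcsin(sn))
    p = s - sn * n_sp
    if np.linalg.norm(p) < 1e-9:
        raise ValueError("span parallel to stroke-plane normal (gimbal pose)")
    phi = np.rad2deg(np.arctan2(np.dot(p, lat), np.dot(p, b_sp)))
    c0, w = _chord_frame(s, n_sp, side)
    psi = np.rad2deg(np.arctan2(np.dot(c, w), np.dot(c, c0)))
    return float(phi), float(theta), float(psi)
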