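"""Articulated fly model, wingbeat kinematics and silhouette rendering.

This module stands in for the high-speed cameras: it builds a parametric
fly (ellipsoidal body + two planar wing outlines attached at hinges),
poses it with prescribed body/wing kinematics, and renders binary
silhouettes on a :class:`~flyhull.cameras.CameraRig`, optionally with
per-part masks and depth labels so tests and the visibility analysis know
the ground-truth occlusion structure.

Rendering is exact per-pixel ray casting: the body is intersected
analytically as a quadric and each wing as a set of planar facets (one
facet for a rigid wing, one thin strip per spanwise station when twist is
requested).  A pixel is foreground iff the ray through its center hits a
surface; depth is the distance from the camera center to the nearest hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from matplotlib.path import Path as _MplPath

from .cameras import CameraModel, CameraRig, project_point
from .conventions import body_rotation, unit, wing_vectors

DEFAULT_BODY_LENGTH = 2.5e-3  # m
DEFAULT_BODY_WIDTH = 1.2e-3  # m
DEFAULT_WING_LENGTH = 2.5e-3  # m
DEFAULT_MAX_CHORD = 1.0e-3  # m
DEFAULT_FRAMES_PER_WINGBEAT = 73
DEFAULT_WINGBEAT_HZ = 220.0


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _wing_outline(
    span: float, max_chord: float, n_stations: int = 16
) -> np.ndarray:
    """Planar fruit-fly-like wing outline in wing coordinates.

    Wing frame: y along the span (hinge at y=0, tip at y=span), x along the
    chord with the leading edge at positive x.  Returns a closed simple
    polygon (M, 2) running root->tip along the LE and tip->root along the TE.
    """
    eta = np.linspace(0.0, 1.0, n_stations + 1)
    # smooth chord profile, max near 55% span, closing at root and tip
    c = max_chord * np.sin(np.pi * eta**0.85) ** 0.9
    x_le = 0.35 * c
    x_te = -0.65 * c
    le = np.column_stack([x_le, eta * span])
    te = np.column_stack([x_te, eta * span])[::-1]
    return np.vstack([le, te[1:-1]])


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a simple 2D polygon."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class FlyModel:
    """Parametric fly: ellipsoidal body and two planar wing outlines.

    ``body_semi_axes`` are the ellipsoid semi-axes along the body frame
    (x forward, y left, z up), in meters.  ``wing_outline`` is a planar
    polygon in wing coordinates (chord x, span y) shared by both wings.
    ``hinge_offsets`` map side (+1 left / -1 right) to the hinge position in
    the body frame.
    """

    body_semi_axes: tuple[float, float, float]
    wing_outline: np.ndarray
    hinge_offsets: dict[int, np.ndarray]
    wing_length: float
    body_length: float
    twist_deg: float = 0.0  # linear spanwise twist, root -> tip

    @property
    def wing_area(self) -> float:
        return polygon_area(self.wing_outline)

    def body_mesh(self, subdivisions: int = 3):
        """Watertight triangulated body surface (trimesh), body frame."""
        import trimesh

        m = trimesh.creation.icosphere(subdivisions=subdivisions)
        m.apply_scale(self.body_semi_axes)
        return m


def build_fly_model(
    body_length: float = DEFAULT_BODY_LENGTH,
    wing_length: float = DEFAULT_WING_LENGTH,
    body_width: float = DEFAULT_BODY_WIDTH,
    body_height: float | None = None,
    max_chord: float = DEFAULT_MAX_CHORD,
    hinge_fraction: float = 0.55,
    twist_deg: float = 0.0,
) -> FlyModel:
    """Build the default articulated fly model.

    ``hinge_fraction`` places the wing hinges at that fraction of the body
    length from the tail.  ``twist_deg`` adds a linear spanwise twist
    (deformation) to both wings; 0 keeps them rigid and planar.
    """
    if body_length <= 0 or wing_length <= 0 or body_width <= 0:
        raise ValueError("model dimensions must be positive")
    if body_height is None:
        body_height = body_width
    outline = _wing_outline(wing_length, max_chord)
    hx = (hinge_fraction - 0.5) * body_length
    hy = 0.45 * body_width
    hz = 0.3 * body_height
    return FlyModel(
        body_semi_axes=(body_length / 2.0, body_width / 2.0, body_height / 2.0),
        wing_outline=outline,
        hinge_offsets={+1: np.array([hx, hy, hz]), -1: np.array([hx, -hy, hz])},
        wing_length=wing_length,
        body_length=body_length,
        twist_deg=twist_deg,
    )


# ---------------------------------------------------------------------------
# poses
# ---------------------------------------------------------------------------

@dataclass
class BodyPose:
    """Body position (m) and orientation (columns = body axes in lab frame)."""

    position: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        r = np.asarray(self.rotation, float)
        if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-9) \
                or np.linalg.det(r) < 0:
            raise ValueError("orientation must be a proper rotation matrix")
        self.rotation = r

    @classmethod
    def from_angles(cls, position, yaw_deg=0.0, pitch_deg=0.0, roll_deg=0.0):
        return cls(np.asarray(position, float),
                   body_rotation(yaw_deg, pitch_deg, roll_deg))

    @property
    def x_b(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def y_b(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def z_b(self) -> np.ndarray:
        return self.rotation[:, 2]


@dataclass
class WingPose:
    """Wing Euler angles (deg) for one side (+1 left, -1 right)."""

    phi: float
    theta: float
    psi: float
    side: int

    def __post_init__(self) -> None:
        if self.side not in (+1, -1):
            raise ValueError("side must be +1 (left) or -1 (right)")
        if not np.all(np.isfinite([self.phi, self.theta, self.psi])):
            raise ValueError("wing angles must be finite")


@dataclass
class PoseSequence:
    """Ground-truth trajectory: per-frame body pose and two wing poses."""

    times: np.ndarray
    body: list[BodyPose]
    left: list[WingPose]
    right: list[WingPose]
    frames_per_wingbeat: int
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("times must increase at a constant interval")
        self.times = t

    def __len__(self) -> int:
        return len(self.times)

    def truth_table(self):
        """Ground truth as a pandas DataFrame (angles in deg, position in m)."""
        import pandas as pd

        from .conventions import body_angles_from_rotation

        rows = []
        for i, t in enumerate(self.times):
            bp = self.body[i]
            yaw, pitch, roll = body_angles_from_rotation(bp.rotation)
            rows.append(
                {
                    "t": t,
                    "x": bp.position[0],
                    "y": bp.position[1],
                    "z": bp.position[2],
                    "yaw": yaw,
                    "pitch": pitch,
                    "roll": roll,
                    "phi_L": self.left[i].phi,
                    "theta_L": self.left[i].theta,
                    "psi_L": self.left[i].psi,
                    "phi_R": self.right[i].phi,
                    "theta_R": self.right[i].theta,
                    "psi_R": self.right[i].psi,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# posing
# ---------------------------------------------------------------------------

@dataclass
class WingFacet:
    """A planar facet: origin point, in-plane basis (u, v), unit normal and
    a 2D polygon in (u, v) coordinates."""

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    normal: np.ndarray
    poly2d: np.ndarray
    _path: _MplPath = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._path = _MplPath(self.poly2d)

    def vertices(self) -> np.ndarray:
        return (
            self.origin
            + self.poly2d[:, 0, None] * self.u
            + self.poly2d[:, 1, None] * self.v
        )


@dataclass
class PosedWing:
    side: int
    hinge: np.ndarray
    span: np.ndarray  # unit span vector, hinge -> tip
    chord: np.ndarray  # unit chord vector at the root, TE -> LE
    facets: list[WingFacet]

    def vertices(self) -> np.ndarray:
        return np.vstack([f.vertices() for f in self.facets])


@dataclass
class PosedFly:
    """Lab-frame surfaces of a posed fly plus ground-truth wing vectors."""

    body_center: np.ndarray
    body_rotation: np.ndarray
    body_semi_axes: np.ndarray
    wings: dict[int, PosedWing]
    model: FlyModel
    body_pose: BodyPose

    def body_vertices(self, subdivisions: int = 2) -> np.ndarray:
        if self.model is not None:
            verts = self.model.body_mesh(subdivisions=subdivisions).vertices
        else:
            # body-only stand-in (no mesh): coarse sphere sampling scaled
            # by the semi-axes, sufficient for projected bounding boxes
            u = np.linspace(0, 2 * np.pi, 16, endpoint=False)
            v = np.linspace(0.0, np.pi, 9)
            uu, vv = np.meshgrid(u, v)
            sphere = np.column_stack([
                (np.sin(vv) * np.cos(uu)).ravel(),
                (np.sin(vv) * np.sin(uu)).ravel(),
                np.cos(vv).ravel(),
            ])
            verts = sphere * np.asarray(self.body_semi_axes)
        return self.body_center + verts @ self.body_rotation.T

    def all_vertices(self) -> np.ndarray:
        return np.vstack(
            [self.body_vertices()] + [w.vertices() for w in self.wings.values()]
        )


def _pose_wing(
    model: FlyModel, body: BodyPose, wp: WingPose
) -> PosedWing:
    s, c = wing_vectors(wp.phi, wp.theta, wp.psi, wp.side, body.x_b, body.y_b)
    hinge = body.position + body.rotation @ model.hinge_offsets[wp.side]
    n = unit(np.cross(s, c))
    facets: list[WingFacet] = []
    outline = model.wing_outline
    if abs(model.twist_deg) < 1e-12:
        facets.append(
            WingFacet(origin=hinge, u=c, v=s, normal=n, poly2d=outline.copy())
        )
    else:
        # split the outline into spanwise strips; each strip is rotated about
        # the span axis by the local twist and treated as planar
        sp = outline[:, 1]
        stations = np.unique(sp)
        m = len(stations) - 1
        le = outline[: m + 1]  # root->tip along LE (construction order)
        # TE runs tip->root in the outline; root and tip vertices are shared
        te = outline[[0, *range(len(outline) - 1, m, -1), m]]
        for k in range(m):
            eta_mid = 0.5 * (stations[k] + stations[k + 1]) / model.wing_length
            tw = np.deg2rad(model.twist_deg * eta_mid)
            c_loc = np.cos(tw) * c + np.sin(tw) * n
            n_loc = unit(np.cross(s, c_loc))
            quad = np.array(
                [
                    [le[k, 0], le[k, 1]],
                    [le[k + 1, 0], le[k + 1, 1]],
                    [te[k + 1, 0], te[k + 1, 1]],
                    [te[k, 0], te[k, 1]],
                ]
            )
            facets.append(
                WingFacet(origin=hinge, u=c_loc, v=s, normal=n_loc, poly2d=quad)
            )
    return PosedWing(side=wp.side, hinge=hinge, span=s, chord=c, facets=facets)


def pose_model(
    model: FlyModel, body: BodyPose, left: WingPose, right: WingPose
) -> PosedFly:
    """Place the fly model in the lab frame.

    The body is rigidly transformed; each wing is rotated about its hinge by
    the wing Euler angles (convention of :mod:`flyhull.conventions`) and
    carried along with the body.  Ground-truth span/chord unit vectors are
    stored on the returned wings.
    """
    if left.side != +1 or right.side != -1:
        raise ValueError("left/right wing poses have wrong sides")
    return PosedFly(
        body_center=body.position,
        body_rotation=body.rotation,
        body_semi_axes=np.asarray(model.body_semi_axes, float),
        wings={+1: _pose_wing(model, body, left),
               -1: _pose_wing(model, body, right)},
        model=model,
        body_pose=body,
    )


# ---------------------------------------------------------------------------
# sequences and ensembles
# ---------------------------------------------------------------------------

@dataclass
class WingbeatSpec:
    """Harmonic wingbeat waveforms (angles in deg, frequency in Hz).

    phi(t)   = mean_phi + amp_phi * cos(2 pi f t)
    theta(t) = amp_theta * cos(4 pi f t + theta_phase)
    psi(t)   = mean_psi + amp_psi * sin(2 pi f t)

    The defaults emulate a typical fruit-fly stroke: ~140 deg peak-to-peak
    stroke amplitude about a 90 deg mean, a small double-frequency elevation
    oscillation, and wing pitch flipping about 90 deg between half-strokes.
    """

    frequency_hz: float = DEFAULT_WINGBEAT_HZ
    mean_phi: float = 90.0
    amp_phi: float = 70.0
    amp_theta: float = 12.0
    theta_phase: float = 0.0
    mean_psi: float = 90.0
    amp_psi: float = 45.0

    def angles(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        w = 2.0 * np.pi * self.frequency_hz * np.asarray(t, float)
        phi = self.mean_phi + self.amp_phi * np.cos(w)
        theta = self.amp_theta * np.cos(2.0 * w + np.deg2rad(self.theta_phase))
        psi = self.mean_psi + self.amp_psi * np.sin(w)
        return phi, theta, psi


@dataclass
class BodyTrajectorySpec:
    """Body trajectory: constants or callables of time (deg / m)."""

    position: Sequence[float] | Callable = (0.0, 0.0, 0.0)
    yaw: float | Callable = 0.0
    pitch: float | Callable = 45.0
    roll: float | Callable = 0.0

    def pose(self, t: float) -> BodyPose:
        def ev(x):
            return x(t) if callable(x) else x

        return BodyPose.from_angles(
            np.asarray(ev(self.position), float), ev(self.yaw), ev(self.pitch),
            ev(self.roll),
        )


def generate_wingbeat_sequence(
    model: FlyModel,
    body_spec: BodyTrajectorySpec | None = None,
    wing_spec: WingbeatSpec | None = None,
    n_wingbeats: int = 2,
    frames_per_wingbeat: int = DEFAULT_FRAMES_PER_WINGBEAT,
    seed: int | None = None,
) -> PoseSequence:
    """Sample a smooth periodic wingbeat trajectory.

    Left and right wings are mirrored (identical Euler angles).  The frame
    interval is ``1 / (frequency * frames_per_wingbeat)``.
    """
    if n_wingbeats < 1:
        raise ValueError("n_wingbeats must be >= 1")
    body_spec = body_spec or BodyTrajectorySpec()
    wing_spec = wing_spec or WingbeatSpec()
    n = n_wingbeats * frames_per_wingbeat
    dt = 1.0 / (wing_spec.frequency_hz * frames_per_wingbeat)
    times = np.arange(n) * dt
    phi, theta, psi = wing_spec.angles(times)
    body = [body_spec.pose(t) for t in times]
    left = [WingPose(p, th, ps, +1) for p, th, ps in zip(phi, theta, psi)]
    right = [WingPose(p, th, ps, -1) for p, th, ps in zip(phi, theta, psi)]
    return PoseSequence(
        times=times,
        body=body,
        left=left,
        right=right,
        frames_per_wingbeat=frames_per_wingbeat,
        seed=seed,
    )


DEFAULT_ENSEMBLE_RANGES = {
    "phi": (-30.0, 160.0),
    "theta": (-30.0, 30.0),
    "psi": (0.0, 180.0),
    "body_pitch": (30.0, 60.0),
    # flies face arbitrary directions; without uniform yaw a rig
    # comparison would depend on the arbitrary fly-to-rig azimuth
    "body_yaw": (0.0, 360.0),
}


def sample_pose_ensemble(
    ranges: dict[str, tuple[float, float]] | None = None,
    n: int = 100,
    seed: int = 0,
) -> list[tuple[BodyPose, WingPose, WingPose]]:
    """Sample ``n`` independent uniform poses from the given angle ranges.

    Left and right wing angles are drawn independently.  Reproducible under
    a fixed seed.
    """
    r = dict(DEFAULT_ENSEMBLE_RANGES)
    if ranges:
        r.update(ranges)
    for key, (lo, hi) in r.items():
        if hi < lo:
            raise ValueError(f"empty range for {key}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        body = BodyPose.from_angles(
            (0.0, 0.0, 0.0),
            yaw_deg=rng.uniform(*r["body_yaw"]),
            pitch_deg=rng.uniform(*r["body_pitch"]),
        )
        wings = []
        for side in (+1, -1):
            wings.append(
                WingPose(
                    phi=rng.uniform(*r["phi"]),
                    theta=rng.uniform(*r["theta"]),
                    psi=rng.uniform(*r["psi"]),
                    side=side,
                )
            )
        out.append((body, wings[0], wings[1]))
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

#: winner-label codes in :attr:`SilhouetteSet.labels`
LABEL_BG, LABEL_BODY, LABEL_LEFT, LABEL_RIGHT = 0, 1, 2, 3


@dataclass
class SilhouetteSet:
    """Rendered views for one camera: binary silhouette, per-part footprint
    masks, nearest-surface labels and depth (distance from camera, m)."""

    full: np.ndarray
    body_mask: np.ndarray
    wing_masks: dict[int, np.ndarray]
    labels: np.ndarray
    depth: np.ndarray

    def visible_wing_mask(self, side: int) -> np.ndarray:
        """Pixels where wing ``side`` is the nearest (unoccluded) surface."""
        return self.labels == (LABEL_LEFT if side == +1 else LABEL_RIGHT)


def _ray_ellipsoid(origin, dirs, center, rotation, semi_axes):
    """Smallest positive ray parameter hitting the ellipsoid, inf on miss."""
    ax = np.asarray(semi_axes, float)
    o = ((origin - center) @ rotation) / ax
    d = (dirs @ rotation) / ax
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * (d @ o)
    c = float(o @ o) - 1.0
    disc = b * b - 4.0 * a * c
    t = np.full(len(dirs), np.inf)
    hit = disc >= 0
    sq = np.sqrt(np.maximum(disc, 0.0))
    t1 = (-b - sq) / (2.0 * a)
    t2 = (-b + sq) / (2.0 * a)
    tt = np.where(t1 > 1e-12, t1, np.where(t2 > 1e-12, t2, np.inf))
    t[hit] = tt[hit]
    return t


def _ray_facet(origin, dirs, facet: WingFacet):
    """Ray parameter at which each ray hits the facet polygon, inf on miss."""
    denom = dirs @ facet.normal
    num = float((facet.origin - origin) @ facet.normal)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    valid = np.isfinite(t) & (t > 1e-12) & (np.abs(denom) > 1e-15)
    out = np.full(len(dirs), np.inf)
    if not np.any(valid):
        return out
    hp = origin + t[valid, None] * dirs[valid]
    rel = hp - facet.origin
    uv = np.column_stack([rel @ facet.u, rel @ facet.v])
    inside = facet._path.contains_points(uv, radius=1e-12)
    idx = np.flatnonzero(valid)[inside]
    out[idx] = t[valid][inside]
    return out


def _render_camera(posed: PosedFly, cam: CameraModel, pad: int = 3) -> SilhouetteSet:
    w, h = cam.image_size
    full = np.zeros((h, w), dtype=bool)
    body_mask = np.zeros((h, w), dtype=bool)
    wing_masks = {+1: np.zeros((h, w), dtype=bool), -1: np.zeros((h, w), bool)}
    labels = np.zeros((h, w), dtype=np.int8)
    depth = np.full((h, w), np.inf, dtype=np.float32)

    verts = posed.all_vertices()
    px = project_point(cam, verts)
    x0 = int(np.floor(px[:, 0].min())) - pad
    x1 = int(np.ceil(px[:, 0].max())) + pad
    y0 = int(np.floor(px[:, 1].min())) - pad
    y1 = int(np.ceil(px[:, 1].max())) + pad
    x0, x1 = max(0, x0), min(w - 1, x1)
    y0, y1 = max(0, y0), min(h - 1, y1)
    if x1 < x0 or y1 < y0:
        import warnings

        warnings.warn(f"camera {cam.id}: model projects outside the image")
        return SilhouetteSet(full, body_mask, wing_masks, labels, depth)

    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    gx, gy = np.meshgrid(xs, ys)
    pix = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    origin = cam.center
    dirs = cam.ray_directions(pix)
    norms = np.linalg.norm(dirs, axis=1)

    t_body = _ray_ellipsoid(
        origin, dirs, posed.body_center, posed.body_rotation,
        posed.body_semi_axes,
    )
    t_wing = {+1: np.full(len(dirs), np.inf),
              -1: np.full(len(dirs), np.inf)}
    for side, wing in posed.wings.items():
        t = np.full(len(dirs), np.inf)
        for facet in wing.facets:
            t = np.minimum(t, _ray_facet(origin, dirs, facet))
        t_wing[side] = t

    shape = gx.shape
    d_body = (t_body * norms).reshape(shape)
    d_left = (t_wing[+1] * norms).reshape(shape)
    d_right = (t_wing[-1] * norms).reshape(shape)
    stack = np.stack([d_body, d_left, d_right])
    nearest = np.argmin(stack, axis=0)
    dmin = np.min(stack, axis=0)
    hit = np.isfinite(dmin)

    sub_labels = np.where(hit, nearest + 1, 0).astype(np.int8)
    sl = (slice(y0, y1 + 1), slice(x0, x1 + 1))
    full[sl] = hit
    body_mask[sl] = np.isfinite(d_body)
    wing_masks[+1][sl] = np.isfinite(d_left)
    wing_masks[-1][sl] = np.isfinite(d_right)
    labels[sl] = sub_labels
    depth[sl] = dmin
    return SilhouetteSet(full, body_mask, wing_masks, labels, depth)


def render_silhouettes(
    posed: PosedFly, rig: CameraRig
) -> dict[int, SilhouetteSet]:
    """Render binary silhouettes (and part masks/labels) for every camera.

    Deterministic for fixed inputs.  Emits a warning and an empty image for
    any camera the model projects entirely outside of.
    """
    return {cam.id: _render_camera(posed, cam) for cam in rig}


def render_sequence(
    model: FlyModel, seq: PoseSequence, rig: CameraRig
) -> list[dict[int, SilhouetteSet]]:
    """Render every frame of a pose sequence (full per-part detail).

    Keeps every camera's depth/label buffers in memory; for long sequences
    prefer :func:`render_stacks`.
    """
    out = []
    for i in range(len(seq)):
        posed = pose_model(model, seq.body[i], seq.left[i], seq.right[i])
        out.append(render_silhouettes(posed, rig))
    return out


def render_stacks(
    model: FlyModel,
    seq: PoseSequence,
    rig: CameraRig,
    with_body_masks: bool = False,
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray] | None]:
    """Render a sequence into compact binary stacks, frame by frame.

    Returns ``(full_stacks, body_stacks)`` mapping camera id to (T, H, W)
    bool arrays; ``body_stacks`` is None unless ``with_body_masks``.
    Memory use stays at one frame's render buffers regardless of length.
    """
    t_n = len(seq)
    full = {
        cam.id: np.zeros((t_n, cam.image_size[1], cam.image_size[0]), bool)
        for cam in rig
    }
    body = (
        {cid: np.zeros_like(arr) for cid, arr in full.items()}
        if with_body_masks else None
    )
    for i in range(t_n):
        posed = pose_model(model, seq.body[i], seq.left[i], seq.right[i])
        views = render_silhouettes(posed, rig)
        for cid, view in views.items():
            full[cid][i] = view.full
            if body is not None:
                body[cid][i] = view.body_mask & view.full
    return full, body


# ---------------------------------------------------------------------------
# ground-truth voxelization (oracle for hull tests)
# ---------------------------------------------------------------------------

def voxelize_posed(
    posed: PosedFly, grid, margin: float | None = None,
    parts: Sequence[str] = ("body", "wings"),
):
    """Ground-truth voxelization of a posed fly on a voxel grid.

    Returns a :class:`~flyhull.hulls.Hull` of voxels whose centers lie
    strictly inside the body (shrunk by ``margin``) and/or voxels containing
    samples of the wing surfaces (outlines shrunk in-plane by ``margin``).
    The margin (default one voxel pitch) keeps the body voxelization clear
    of the silhouette boundary; for the planar wings membership of voxels
    straddling the surface is inherently ambiguous at finite pixel size
    (a hull can only be guaranteed to contain the object eroded by one
    pixel footprint, and a zero-thickness surface has empty erosion), so
    wing containment should be asserted as a coverage fraction, not
    exactly.  ``parts`` selects which surfaces contribute.
    """
    from shapely.geometry import Polygon

    from .hulls import Hull

    if margin is None:
        margin = grid.pitch
    flats = []
    if "body" in parts:
        # body: voxel centers inside the shrunken ellipsoid
        idx = grid.all_indices()
        pts = grid.voxel_centers(idx)
        ax = np.maximum(posed.body_semi_axes - margin, 1e-9)
        q = ((pts - posed.body_center) @ posed.body_rotation) / ax
        inside = np.einsum("ij,ij->i", q, q) <= 1.0
        flats.append(grid.flat(idx[inside]))
    if "wings" not in parts:
        return Hull(
            grid, np.concatenate(flats) if flats else np.empty(0, np.int64)
        )
    # wings: dense surface samples of each shrunken facet polygon
    step = grid.pitch / 2.0
    for wing in posed.wings.values():
        for facet in wing.facets:
            poly = Polygon(facet.poly2d).buffer(-margin)
            if poly.is_empty:
                continue
            minx, miny, maxx, maxy = poly.bounds
            us = np.arange(minx, maxx + step, step)
            vs = np.arange(miny, maxy + step, step)
            uu, vv = np.meshgrid(us, vs)
            uv = np.column_stack([uu.ravel(), vv.ravel()])
            inside2 = _MplPath(np.asarray(poly.exterior.coords)).contains_points(uv)
            uv = uv[inside2]
            if len(uv) == 0:
                continue
            lab = (
                facet.origin
                + uv[:, 0, None] * facet.u
                + uv[:, 1, None] * facet.v
            )
            vidx = grid.point_to_index(lab)
            ok = np.all((vidx >= 0) & (vidx < np.asarray(grid.dims)), axis=1)
            if np.any(ok):
                flats.append(grid.flat(vidx[ok]))
    return Hull(grid, np.concatenate(flats) if flats else np.empty(0, np.int64))
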