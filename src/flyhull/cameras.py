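"""Camera projection model, rig presets and calibration I/O.

Each camera is a pinhole described by a single 3x4 DLT-style projection
matrix ``P`` mapping homogeneous lab-frame points (meters) to homogeneous
pixel coordinates.  No lens distortion is modeled; real-data users should
pre-undistort their images.

Rig presets (all aimed at a common look-at point, default the origin):

``cartesian3``
    Three cameras along the lab +x, +y and +z axes (mutually orthogonal
    optical axes, the common "side, front, top" arrangement).
``pyramidal3``
    Three cameras elevated symmetrically above the chamber with mutually
    orthogonal optical axes; azimuths 120 deg apart, elevation
    atan(1/sqrt(2)) ~ 35.26 deg.
``pyramidal4``
    Four cameras with four-fold azimuthal symmetry at the same elevation.
``hybrid4``
    The pyramidal3 triplet plus one vertical (top-down) camera.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conventions import unit

PRESETS = ("cartesian3", "pyramidal3", "pyramidal4", "hybrid4")

#: elevation (deg) making three azimuthally symmetric optical axes orthogonal
PYRAMIDAL_ELEVATION_DEG = float(np.rad2deg(np.arctan(1.0 / np.sqrt(2.0))))


class DegenerateProjectionError(ValueError):
    """Raised when a point projects with (near-)zero homogeneous depth."""


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: ``id``, 3x4 projection matrix ``P``, image size."""

    id: int
    P: np.ndarray
    image_size: tuple[int, int]  # (width, height)

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (3, 4):
            raise ValueError(f"camera {self.id}: P must be 3x4, got {P.shape}")
        if not np.all(np.isfinite(P)):
            raise ValueError(f"camera {self.id}: non-finite entries in P")
        if np.linalg.matrix_rank(P) != 3:
            raise ValueError(f"camera {self.id}: P must have rank 3")
        object.__setattr__(self, "P", P)

    @property
    def center(self) -> np.ndarray:
        """Camera center in lab coordinates (right null space of P)."""
        _, _, vt = np.linalg.svd(self.P)
        c = vt[-1]
        if abs(c[3]) < 1e-12:
            raise ValueError("camera at infinity")
        return c[:3] / c[3]

    def ray_directions(self, pixels: np.ndarray) -> np.ndarray:
        """Lab-frame direction vectors of the viewing rays through ``pixels``.

        Directions are oriented away from the camera (positive depth).
        """
        px = np.atleast_2d(np.asarray(pixels, dtype=float))
        h = np.column_stack([px, np.ones(len(px))])
        m = self.P[:, :3]
        d = np.linalg.solve(m, h.T).T
        # orient so points at positive depth project with positive w
        if np.linalg.det(m) < 0:
            d = -d
        return d


@dataclass
class CameraRig:
    """An ordered collection of cameras with a preset label."""

    cameras: list[CameraModel]
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.cameras]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate camera ids: {ids}")

    def __len__(self) -> int:
        return len(self.cameras)

    def __iter__(self):
        return iter(self.cameras)

    def __getitem__(self, i: int) -> CameraModel:
        return self.cameras[i]


def project_point(camera: CameraModel, point: np.ndarray) -> np.ndarray:
    """Project lab-frame point(s) (meters) to continuous pixel coordinates.

    Accepts a single (3,) point or an (N, 3) array; returns matching shape
    with 2 columns.  Raises :class:`DegenerateProjectionError` when the
    homogeneous depth vanishes (point at/behind the camera plane through the
    center).
    """
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    h = camera.P @ np.column_stack([pts, np.ones(len(pts))]).T
    w = h[2]
    if np.any(np.abs(w) < 1e-12):
        raise DegenerateProjectionError(
            f"camera {camera.id}: zero homogeneous depth (point at camera plane)"
        )
    px = (h[:2] / w).T
    return px[0] if single else px


def round_pixels(pixels: np.ndarray) -> np.ndarray:
    """Round continuous pixels half-away-from-zero to integer indices."""
    p = np.asarray(pixels, dtype=float)
    return np.trunc(p + np.copysign(0.5, p)).astype(np.int64)


def project_voxels(
    camera: CameraModel, grid, indices: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Project voxel centers to rounded integer pixels.

    Parameters
    ----------
    grid : VoxelGrid
        Grid whose voxel centers are projected.
    indices : (N, 3) int array, optional
        Voxel indices; defaults to every voxel in the grid.

    Returns
    -------
    pixels : (N, 2) int array of rounded (x, y) pixel coordinates.
    in_image : (N,) bool array, False where the pixel falls outside the
        camera's image bounds.
    """
    if indices is None:
        indices = grid.all_indices()
    indices = np.asarray(indices)
    if indices.size == 0:
        return np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=bool)
    pts = grid.voxel_centers(indices)
    px = round_pixels(project_point(camera, pts))
    w, h = camera.image_size
    in_image = (px[:, 0] >= 0) & (px[:, 0] < w) & (px[:, 1] >= 0) & (px[:, 1] < h)
    return px, in_image


def _look_at_camera(
    cam_id: int,
    position: np.ndarray,
    target: np.ndarray,
    focal_px: float,
    image_size: tuple[int, int],
) -> CameraModel:
    """Build a pinhole camera at ``position`` aimed at ``target``."""
    position = np.asarray(position, float)
    target = np.asarray(target, float)
    z_cam = unit(target - position)  # optical axis, toward the scene
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(z_cam, up)) > 1.0 - 1e-9:
        up = np.array([1.0, 0.0, 0.0])
    x_cam = unit(np.cross(z_cam, up))
    y_cam = np.cross(z_cam, x_cam)  # right-handed, image y "down"
    R = np.vstack([x_cam, y_cam, z_cam])
    w, h = image_size
    K = np.array(
        [
            [focal_px, 0.0, (w - 1) / 2.0],
            [0.0, focal_px, (h - 1) / 2.0],
            [0.0, 0.0, 1.0],
        ]
    )
    P = K @ np.column_stack([R, -R @ position])
    return CameraModel(id=cam_id, P=P, image_size=(w, h))


def make_rig(
    preset_name: str,
    distance: float = 0.15,
    image_size: tuple[int, int] = (256, 256),
    pixel_pitch: float = 40e-6,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> CameraRig:
    """Build one of the preset camera rigs.

    Parameters
    ----------
    distance : float
        Camera distance from the look-at point (m).
    pixel_pitch : float
        Physical size (m) of one pixel at the look-at point; the focal
        length in pixels is ``distance / pixel_pitch``.
    """
    center = np.asarray(center, float)
    el = np.deg2rad(PYRAMIDAL_ELEVATION_DEG)

    def ring(azimuths_deg, elevation_rad):
        out = []
        for az in azimuths_deg:
            a = np.deg2rad(az)
            u = np.array(
                [
                    np.cos(elevation_rad) * np.cos(a),
                    np.cos(elevation_rad) * np.sin(a),
                    np.sin(elevation_rad),
                ]
            )
            out.append(center + distance * u)
        return out

    if preset_name == "cartesian3":
        positions = [
            center + distance * np.array([1.0, 0.0, 0.0]),
            center + distance * np.array([0.0, 1.0, 0.0]),
            center + distance * np.array([0.0, 0.0, 1.0]),
        ]
    elif preset_name == "pyramidal3":
        positions = ring([0.0, 120.0, 240.0], el)
    elif preset_name == "pyramidal4":
        positions = ring([0.0, 90.0, 180.0, 270.0], el)
    elif preset_name == "hybrid4":
        positions = ring([0.0, 120.0, 240.0], el)
        positions.append(center + distance * np.array([0.0, 0.0, 1.0]))
    else:
        raise ValueError(
            f"unknown preset {preset_name!r}; choose one of {PRESETS}"
        )
    focal_px = distance / pixel_pitch
    cams = [
        _look_at_camera(j + 1, pos, center, focal_px, image_size)
        for j, pos in enumerate(positions)
    ]
    return CameraRig(cameras=cams, preset_name=preset_name)


# ---------------------------------------------------------------------------
# calibration I/O
# ---------------------------------------------------------------------------

def write_calibration(rig: CameraRig, path) -> None:
    """Write a rig to the documented calibration JSON schema."""
    payload = {
        "preset": rig.preset_name,
        "cameras": [
            {
                "id": cam.id,
                "P": [float(x) for x in cam.P.ravel()],
                "width": cam.image_size[0],
                "height": cam.image_size[1],
            }
            for cam in rig
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_calibration(path) -> CameraRig:
    """Read a calibration JSON file; validates entry counts and finiteness."""
    with open(path) as fh:
        payload = json.load(fh)
    cams = []
    for entry in payload["cameras"]:
        cam_id = entry.get("id", "?")
        p = entry.get("P", [])
        if len(p) != 12:
            raise ValueError(
                f"camera {cam_id}: expected 12 projection-matrix entries, "
                f"got {len(p)}"
            )
        P = np.asarray(p, dtype=float).reshape(3, 4)
        if not np.all(np.isfinite(P)):
            raise ValueError(f"camera {cam_id}: non-finite matrix entries")
        cams.append(
            CameraModel(
                id=int(cam_id),
                P=P,
                image_size=(int(entry["width"]), int(entry["height"])),
            )
        )
    return CameraRig(cameras=cams, preset_name=payload.get("preset", "custom"))


def triangulate_point(
    cameras: Sequence[CameraModel], pixels: Sequence[np.ndarray]
) -> tuple[np.ndarray, float]:
    """Least-squares triangulation of one 3D point from >=2 pixel sightings.

    Uses the standard homogeneous DLT system; returns the point and the RMS
    reprojection residual in pixels.
    """
    if len(cameras) < 2:
        raise ValueError("triangulation requires at least two cameras")
    rows = []
    for cam, (u, v) in zip(cameras, pixels):
        P = cam.P
        rows.append(u * P[2] - P[0])
        rows.append(v * P[2] - P[1])
    a = np.asarray(rows)
    _, _, vt = np.linalg.svd(a)
    x = vt[-1]
    point = x[:3] / x[3]
    resid = []
    for cam, px in zip(cameras, pixels):
        resid.append(project_point(cam, point) - np.asarray(px, float))
    rms = float(np.sqrt(np.mean(np.concatenate(resid) ** 2)))
    return point, rms
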