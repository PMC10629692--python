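"""Camera-configuration occlusion analysis.

Quantifies how well each candidate rig sees the wings over an ensemble of
fly poses, using two per-camera visibility metrics:

* **area**: percentage of the wing's projected area not occluded by the
  body or the other wing;
* **boundary**: percentage of sampled wing-outline points whose nearest
  surface along the viewing ray is the wing itself.

A pose counts as successfully identifiable at a visibility threshold when,
for each wing, the fraction of boundary points seen by at least three
cameras exceeds the threshold; the success fraction over the ensemble as a
function of the threshold is the configuration's success curve.  More and
better-placed cameras shift the curve up; the hybrid four-camera rig
(pyramidal triplet plus a vertical camera) dominates the alternatives on
typical fruit-fly stroke ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cameras import CameraRig, project_point, round_pixels
from .synthetic_fly import (
    LABEL_LEFT,
    LABEL_RIGHT,
    BodyPose,
    FlyModel,
    PosedFly,
    WingPose,
    build_fly_model,
    pose_model,
    render_silhouettes,
    sample_pose_ensemble,
)


@dataclass
class VisibilityRecord:
    """Visibility of one wing in one camera for one pose."""

    pose_id: int
    camera_id: int
    side: int  # +1 left, -1 right
    area_visible_pct: float
    boundary_visible_pct: float
    degenerate: bool = False  # wing projected to fewer than 3 px

    def __post_init__(self) -> None:
        for v in (self.area_visible_pct, self.boundary_visible_pct):
            if not (0.0 <= v <= 100.0 or np.isnan(v)):
                raise ValueError("visibility percentages must be in [0, 100]")


@dataclass
class SuccessCurve:
    """Success fraction of an ensemble versus the visibility threshold."""

    rig_preset: str
    thresholds: np.ndarray  # percent, ascending
    success_fraction: np.ndarray

    def __post_init__(self) -> None:
        d = np.diff(self.success_fraction)
        if np.any(d > 1e-12):
            raise ValueError("success fraction must be non-increasing")


def _outline_points_3d(
    posed: PosedFly, side: int, n_points: int
) -> np.ndarray:
    """Equally spaced sample points along the wing outline, lab frame."""
    wing = posed.wings[side]
    facet = wing.facets[0]
    poly = facet.poly2d
    if len(wing.facets) > 1:
        # twisted wing: use the union outline of the strip facets' LE/TE
        poly = np.vstack([f.poly2d for f in wing.facets])
    closed = np.vstack([poly, poly[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    pts2 = np.empty((n_points, 2))
    j = 0
    for i, t in enumerate(targets):
        while cum[j + 1] < t:
            j += 1
        f = (t - cum[j]) / max(seglen[j], 1e-30)
        pts2[i] = closed[j] + f * seg[j]
    return (
        facet.origin
        + pts2[:, 0, None] * facet.u
        + pts2[:, 1, None] * facet.v
    )


def wing_visibility(
    posed: PosedFly,
    rig: CameraRig,
    n_boundary_points: int = 100,
    pose_id: int = 0,
    views=None,
) -> list[VisibilityRecord]:
    """Per-camera, per-wing visibility of a posed fly.

    The area metric compares the unoccluded (nearest-surface) wing pixels
    with the wing's own full projection; the boundary metric projects
    ``n_boundary_points`` fixed 3D outline samples and checks, with a
    one-pixel tolerance, that the z-buffer winner at the projected pixel is
    the wing itself.
    """
    if views is None:
        views = render_silhouettes(posed, rig)
    records = []
    for cam in rig:
        view = views[cam.id]
        for side in (+1, -1):
            label = LABEL_LEFT if side == +1 else LABEL_RIGHT
            proj = view.wing_masks[side]
            total = int(proj.sum())
            if total < 3:
                records.append(
                    VisibilityRecord(pose_id, cam.id, side, np.nan, np.nan,
                                     degenerate=True)
                )
                continue
            vis = int((view.labels == label).sum())
            area_pct = 100.0 * vis / total
            pts3 = _outline_points_3d(posed, side, n_boundary_points)
            px = round_pixels(project_point(cam, pts3))
            n_vis = int(
                _points_see_label(view.labels, px, label).sum()
            )
            records.append(
                VisibilityRecord(
                    pose_id, cam.id, side,
                    area_pct, 100.0 * n_vis / n_boundary_points,
                )
            )
    return records


def _points_see_label(labels: np.ndarray, px: np.ndarray,
                      label: int) -> np.ndarray:
    """True where the z-buffer winner within 1 px of each point is
    ``label`` (vectorized 3x3 neighborhood test)."""
    h, w = labels.shape
    out = np.zeros(len(px), dtype=bool)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            x = np.clip(px[:, 0] + dx, 0, w - 1)
            y = np.clip(px[:, 1] + dy, 0, h - 1)
            out |= labels[y, x] == label
    # points projecting outside the image are never visible
    inside = (px[:, 0] >= -1) & (px[:, 0] <= w) & (px[:, 1] >= -1) \
        & (px[:, 1] <= h)
    return out & inside


def boundary_visibility_counts(
    posed: PosedFly, rig: CameraRig, n_boundary_points: int = 100,
    views=None,
) -> dict[int, np.ndarray]:
    """Per-wing: number of cameras that see each fixed 3D boundary point."""
    if views is None:
        views = render_silhouettes(posed, rig)
    out = {}
    for side in (+1, -1):
        label = LABEL_LEFT if side == +1 else LABEL_RIGHT
        pts3 = _outline_points_3d(posed, side, n_boundary_points)
        counts = np.zeros(n_boundary_points, dtype=int)
        for cam in rig:
            view = views[cam.id]
            px = round_pixels(project_point(cam, pts3))
            counts += _points_see_label(view.labels, px, label)
        out[side] = counts
    return out


def success_fraction(
    ensemble: list[tuple[BodyPose, WingPose, WingPose]],
    rig: CameraRig,
    thresholds: np.ndarray | None = None,
    model: FlyModel | None = None,
    n_boundary_points: int = 100,
    min_cameras: int = 3,
) -> SuccessCurve:
    """Success curve of one rig over a pose ensemble.

    A pose succeeds at a threshold when, for each wing, the fraction of
    boundary points visible in at least ``min_cameras`` cameras exceeds
    the threshold.
    """
    if len(rig) < min_cameras:
        raise ValueError(
            f"success criterion needs at least {min_cameras} cameras; rig "
            f"has {len(rig)}"
        )
    if not ensemble:
        raise ValueError("ensemble is empty")
    model = model or build_fly_model()
    thresholds = (
        np.linspace(0.0, 100.0, 21) if thresholds is None
        else np.asarray(thresholds, float)
    )
    fractions = []
    for body, wl, wr in ensemble:
        posed = pose_model(model, body, wl, wr)
        counts = boundary_visibility_counts(
            posed, rig, n_boundary_points=n_boundary_points
        )
        fractions.append(
            min(
                float(np.mean(counts[+1] >= min_cameras)),
                float(np.mean(counts[-1] >= min_cameras)),
            )
        )
    fractions = np.asarray(fractions) * 100.0
    success = np.array(
        [float(np.mean(fractions > thr)) for thr in thresholds]
    )
    return SuccessCurve(
        rig_preset=rig.preset_name,
        thresholds=thresholds,
        success_fraction=success,
    )


def compare_rigs(
    ensemble: list[tuple[BodyPose, WingPose, WingPose]],
    rigs: list[CameraRig],
    thresholds: np.ndarray | None = None,
    model: FlyModel | None = None,
    n_boundary_points: int = 100,
) -> pd.DataFrame:
    """Tabulated success curves for several rigs with a dominance summary.

    Returns a long-format DataFrame (rig, threshold, success_fraction,
    best_rig) with one row per rig and threshold.
    """
    if len(rigs) < 2:
        raise ValueError("need at least two rigs to compare")
    curves = [
        success_fraction(
            ensemble, rig, thresholds=thresholds, model=model,
            n_boundary_points=n_boundary_points,
        )
        for rig in rigs
    ]
    thr = curves[0].thresholds
    rows = []
    for i, t in enumerate(thr):
        vals = {c.rig_preset: c.success_fraction[i] for c in curves}
        best = max(vals, key=vals.get)
        for c in curves:
            rows.append(
                {
                    "rig": c.rig_preset,
                    "threshold_pct": float(t),
                    "success_fraction": float(c.success_fraction[i]),
                    "best_rig": best,
                }
            )
    return pd.DataFrame(rows)


def plot_success_curves(df: pd.DataFrame, ax=None):
    """Plot success curves from a :func:`compare_rigs` table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for rig, sub in df.groupby("rig"):
        ax.plot(sub["threshold_pct"], sub["success_fraction"], label=rig)
    ax.set_xlabel("visibility threshold (%)")
    ax.set_ylabel("fraction of poses identified")
    ax.legend()
    return ax
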