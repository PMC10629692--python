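"""Per-wing geometric feature extraction from voxel hulls.

The estimation ladder refines each quantity in stages:

1. body axis and CM from the body hull (PCA + head/tail blob refinement);
2. wing CM from a radial voxel strip at 0.40-0.65 of the wing length;
3. wing tip, first as the farthest voxel from the body CM, then refined as
   the centroid of the base of a cone of voxels around the provisional span;
4. initial chord from k=2 clustering of the strip voxels, followed by one
   re-cut of the strip perpendicular to the updated span;
5. reprojection of the wing hull into every image plane, which recovers
   wing pixels occluded by the body or the other wing in that view;
6. classification of the reprojected boundary into leading/trailing edge,
   carving of the LE/TE edge hulls, local chord vectors along the span
   (wing deformation) and a least-squares wing plane with the final chord.

All direction vectors are unit length; angles are degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_closing, binary_dilation, binary_erosion
from sklearn.cluster import KMeans

from .cameras import CameraModel, CameraRig, project_point, round_pixels
from .conventions import unit
from .hulls import Hull, HullCarver

STRIP_BOUNDS = (0.40, 0.65)  # radial strip for the wing CM, in wing lengths
STRIP_FALLBACK = (0.35, 0.70)  # widened once when the strip is empty
CONE_HALF_ANGLE_DEG = 30.0  # tip-refinement cone half-angle
CONE_BASE_FRACTION = 0.8  # base region: beyond this fraction of max extent
#: max rms (voxel pitches) of mid-chord points about their fitted line for
#: the edge-based refinement to be trusted; a clean planform's mid-chord
#: bow stays within ~2 pitches at the default geometry, other-wing
#: contamination is far larger
MIDLINE_RMS_MAX_PITCHES = 2.0


@dataclass
class WingState:
    """Geometric state of one wing in one frame."""

    side: int  # +1 left, -1 right
    cm: np.ndarray  # R_cm,w (m)
    tip: np.ndarray  # r_tip (m)
    span: np.ndarray  # unit span vector, body -> tip
    chord: np.ndarray  # unit chord vector, TE -> LE
    wing_length: float
    hull: Hull | None = None
    le_hull: Hull | None = None
    te_hull: Hull | None = None
    local_chords: list[tuple[float, np.ndarray, float]] = field(
        default_factory=list
    )  # (span station in [0,1], unit chord, local pitch psi_k deg)
    plane_normal: np.ndarray | None = None
    plane_rms: float = np.nan
    flags: set[str] = field(default_factory=set)
    velocity_oriented: bool = False  # LE side fixed by a real tip velocity
    midline_rms_pitches: float = np.nan  # edge-refinement quality signal


# ---------------------------------------------------------------------------
# body axis
# ---------------------------------------------------------------------------

def head_tail_refine(
    h_body: Hull,
    prev_x_b: np.ndarray | None = None,
    flight_direction: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, Hull, Hull]:
    """Body CM and long axis from the body hull.

    The initial axis is the first principal component of the voxel
    coordinates; head and tail blobs are the front/back quartiles along it,
    and the refined axis is the unit vector from the tail-blob CM to the
    head-blob CM, with the body CM at their midpoint.  Head/tail identity
    comes from ``prev_x_b`` (temporal continuity) or, on the first frame,
    from ``flight_direction``.

    Returns ``(R_cm_b, x_b, head_blob, tail_blob)``.
    """
    if len(h_body) == 0:
        raise ValueError("body hull is empty")
    pts = h_body.points
    cm0 = pts.mean(axis=0)
    cov = np.cov((pts - cm0).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    if evals[-1] < 2.0 * evals[-2]:
        warnings.warn("body hull nearly spherical: axis from PCA only")
    ref = prev_x_b if prev_x_b is not None else flight_direction
    if ref is not None and float(np.dot(axis, ref)) < 0:
        axis = -axis
    t = (pts - cm0) @ axis
    q1, q3 = np.percentile(t, [25, 75])
    head_pts = pts[t >= q3]
    tail_pts = pts[t <= q1]
    head_cm = head_pts.mean(axis=0)
    tail_cm = tail_pts.mean(axis=0)
    x_b = unit(head_cm - tail_cm)
    if prev_x_b is not None and float(np.dot(x_b, prev_x_b)) < 0:
        x_b = -x_b  # continuity guard against blob-assignment flips
        head_cm, tail_cm = tail_cm, head_cm
    r_cm_b = 0.5 * (head_cm + tail_cm)
    grid = h_body.grid
    head = Hull.from_indices(grid, grid.point_to_index(head_pts))
    tail = Hull.from_indices(grid, grid.point_to_index(tail_pts))
    return r_cm_b, x_b, head, tail


def body_axis_carve_bias(
    carver: HullCarver,
    axis: np.ndarray,
    semi_axes: tuple[float, float, float],
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Systematic body-axis error of the carve+blob estimator at a given
    orientation.

    The visual hull of the body is fatter along directions no camera
    cuts; those directions are fixed in the rig frame, so as the body
    rotates the head/tail-blob axis is pulled toward a rig-anchored
    attractor — a gain-like error that grows with the body angles and is
    not removed by a constant offset.  This function measures that bias
    by rendering a reference spheroid (semi-axes ``semi_axes``, axially
    symmetric so roll is irrelevant) at orientation ``axis``, carving it
    through the same projections, and running the same axis estimator.

    Returns the small error vector ``est - axis`` (lab frame); subtracting
    it from a measured axis removes the rig-geometry bias to first order.
    """
    from .conventions import unit as _unit
    from .synthetic_fly import PosedFly, _render_camera

    axis = _unit(np.asarray(axis, float))
    grid = carver.grid
    if center is None:
        center = np.asarray(grid.origin) + (
            np.asarray(grid.dims) - 1) * grid.pitch / 2.0
    # rotation taking x to the axis (roll-free for a spheroid)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 1 - 1e-9:
        ref = np.array([0.0, 1.0, 0.0])
    y = _unit(np.cross(ref, axis))
    rot = np.column_stack([axis, y, np.cross(axis, y)])
    posed = PosedFly(
        body_center=np.asarray(center, float),
        body_rotation=rot,
        body_semi_axes=np.asarray(semi_axes, float),
        wings={},
        model=None,
        body_pose=None,
    )
    masks = {}
    for cam in carver.rig:
        view = _render_camera(posed, cam)
        masks[cam.id] = view.body_mask
    hull = carver.carve(masks)
    if len(hull) == 0:
        return np.zeros(3)
    _, est, _, _ = head_tail_refine(hull, flight_direction=axis)
    return est - axis


# ---------------------------------------------------------------------------
# strip / tip / span / initial chord
# ---------------------------------------------------------------------------

def wing_strip(
    h_wing: Hull,
    r_cm_b: np.ndarray,
    wing_length: float,
    bounds: tuple[float, float] = STRIP_BOUNDS,
) -> tuple[Hull, bool]:
    """Radial voxel strip at ``bounds`` of the wing length from the body CM.

    Returns ``(strip, used_fallback)``.  An empty strip triggers one widened
    attempt (:data:`STRIP_FALLBACK`); if still empty the wing is
    unresolvable this frame (``ValueError``).
    """
    if wing_length <= 0:
        raise ValueError("wing_length must be positive")
    d = np.linalg.norm(h_wing.points - np.asarray(r_cm_b, float), axis=1)
    sel = (d >= bounds[0] * wing_length) & (d <= bounds[1] * wing_length)
    if sel.any():
        return Hull(h_wing.grid, h_wing.flat_indices[sel], _sorted=True), False
    lo, hi = STRIP_FALLBACK
    sel = (d >= lo * wing_length) & (d <= hi * wing_length)
    if sel.any():
        warnings.warn("empty wing strip: widened bounds once")
        return Hull(h_wing.grid, h_wing.flat_indices[sel], _sorted=True), True
    raise ValueError("wing strip empty even after widening: wing unresolvable")


def estimate_span_tip(
    h_wing: Hull,
    strip: Hull,
    r_cm_b: np.ndarray,
    cone_half_angle_deg: float = CONE_HALF_ANGLE_DEG,
    cone_base_fraction: float = CONE_BASE_FRACTION,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, set[str]]:
    """Wing CM, tip and span vector with cone-based tip refinement.

    The provisional tip is the farthest wing voxel from the body CM; the
    refined tip is the centroid of the voxels inside a cone (apex at the
    wing CM, axis along the provisional span, half-angle
    ``cone_half_angle_deg``) beyond ``cone_base_fraction`` of the maximum
    radial extent.  Returns ``(R_cm_w, r_tip, s, flags)``.
    """
    flags: set[str] = set()
    r_cm_b = np.asarray(r_cm_b, float)
    cm_w = strip.centroid()
    pts = h_wing.points
    tip0 = pts[int(np.argmax(np.linalg.norm(pts - r_cm_b, axis=1)))]
    rel0 = tip0 - cm_w
    if np.linalg.norm(rel0) < 1e-12:
        flags.add("span_undefined")
        return cm_w, tip0, np.full(3, np.nan), flags
    s = unit(rel0)
    rel = pts - cm_w
    r = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore"):
        cosang = (rel @ s) / np.where(r > 0, r, np.inf)
    in_cone = cosang >= np.cos(np.deg2rad(cone_half_angle_deg))
    if in_cone.any():
        r_max = r[in_cone].max()
        base = in_cone & (r >= cone_base_fraction * r_max)
        if base.any():
            tip = pts[base].mean(axis=0)
            s = unit(tip - cm_w)
            return cm_w, tip, s, flags
    flags.add("cone_empty")
    return cm_w, tip0, s, flags


def estimate_chord_initial(
    strip: Hull,
    s: np.ndarray,
    orient_toward: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, set[str]]:
    """Initial chord from k=2 clustering of the strip voxels.

    The chord is the unit vector between the two cluster CMs, projected
    perpendicular to the span ``s``.  Its sign is chosen so the chord points
    from the trailing to the leading side: positive dot product with
    ``orient_toward`` (typically the tip velocity) when provided.
    """
    flags: set[str] = set()
    pts = strip.points
    if len(pts) < 2:
        raise ValueError("strip must contain at least two voxels")
    # deterministic init: extreme voxels along the widest direction
    # perpendicular to the span
    perp = pts - np.outer((pts - pts.mean(0)) @ s, s) - pts.mean(0)
    cov = np.cov(perp.T)
    w_dir = np.linalg.eigh(cov)[1][:, -1]
    proj = pts @ w_dir
    init = np.vstack([pts[np.argmax(proj)], pts[np.argmin(proj)]])
    if np.linalg.norm(init[0] - init[1]) < 1e-12:
        init = init + np.array([[1e-9, 0, 0], [-1e-9, 0, 0]])
    km = KMeans(n_clusters=2, init=init, n_init=1, random_state=seed).fit(pts)
    c1, c2 = km.cluster_centers_
    if np.linalg.norm(c1 - c2) < 2.0 * strip.grid.pitch:
        flags.add("chord_clusters_inseparable")
        raise _ChordDeferred(flags)
    c = c1 - c2
    c = c - float(np.dot(c, s)) * np.asarray(s, float)
    if np.linalg.norm(c) < 1e-12:
        flags.add("chord_clusters_inseparable")
        raise _ChordDeferred(flags)
    c = unit(c)
    if orient_toward is not None and float(np.dot(c, orient_toward)) < 0:
        c = -c
    return c, flags


class _ChordDeferred(Exception):
    """Initial chord deferred to the LE/TE stage."""

    def __init__(self, flags: set[str]):
        self.flags = flags


# ---------------------------------------------------------------------------
# reprojection and LE/TE
# ---------------------------------------------------------------------------

def reproject_wing(
    h_wing: Hull,
    rig: CameraRig,
    carver: HullCarver | None = None,
) -> dict[int, np.ndarray]:
    """Reproject a wing hull into every image plane.

    The hull combines information from all views, so the reprojected pixel
    masks also cover wing pixels occluded by the body or the other wing in
    a given view.  Masks are morphologically closed (one iteration) to seal
    single-pixel rounding gaps.
    """
    out = {}
    for cam in rig:
        w, h = cam.image_size
        mask = np.zeros((h, w), dtype=bool)
        if len(h_wing) > 0:
            if carver is not None:
                flat = carver._pix[cam.id][h_wing.flat_indices]
                ok = carver._ok[cam.id][h_wing.flat_indices]
                mask.ravel()[flat[ok]] = True
            else:
                px = round_pixels(project_point(cam, h_wing.points))
                ok = (
                    (px[:, 0] >= 0) & (px[:, 0] < w)
                    & (px[:, 1] >= 0) & (px[:, 1] < h)
                )
                mask[px[ok, 1], px[ok, 0]] = True
            mask = binary_closing(mask, structure=np.ones((3, 3)), iterations=1)
        out[cam.id] = mask
    return out


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one background 4-neighbor."""
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    return mask & ~binary_erosion(mask, structure=cross, border_value=0)


def extract_le_te(
    reprojected: dict[int, np.ndarray],
    rig: CameraRig,
    wing_cm: np.ndarray,
    tip: np.ndarray,
    tip_velocity: np.ndarray | None,
    prev_le_sign: dict[int, float] | None = None,
    min_span_px: float = 3.0,
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray], dict[int, float]]:
    """Split each view's reprojected wing boundary into LE and TE pixels.

    The boundary is divided by the image line through the projected wing CM
    along the projected span; the side containing the projected tip-velocity
    direction is the leading edge.  When the tip velocity is unavailable or
    near zero (stroke reversal), the previous frame's side sign is held.
    Views where the projected span is shorter than ``min_span_px`` are
    dropped (wing seen edge-on).

    Returns ``(le_masks, te_masks, le_signs)`` over the usable cameras.
    """
    le_masks: dict[int, np.ndarray] = {}
    te_masks: dict[int, np.ndarray] = {}
    signs: dict[int, float] = {}
    for cam in rig:
        mask = reprojected.get(cam.id)
        if mask is None or not mask.any():
            continue
        cm2 = project_point(cam, wing_cm)
        tip2 = project_point(cam, tip)
        span2 = tip2 - cm2
        if np.linalg.norm(span2) < min_span_px:
            continue  # edge-on in this view
        n2 = np.array([-span2[1], span2[0]])
        n2 = n2 / np.linalg.norm(n2)
        sign = None
        if tip_velocity is not None and np.linalg.norm(tip_velocity) > 0:
            v2 = project_point(cam, tip + 1e-4 * unit(tip_velocity)) - tip2
            sv = float(np.dot(v2, n2))
            if abs(sv) > 1e-9:
                sign = np.sign(sv)
        if sign is None:
            if prev_le_sign is not None and cam.id in prev_le_sign:
                sign = prev_le_sign[cam.id]
            else:
                sign = 1.0
        bnd = boundary_pixels(mask)
        ys, xs = np.nonzero(bnd)
        side_val = (np.column_stack([xs, ys]) - cm2) @ n2 * sign
        le = np.zeros_like(mask)
        te = np.zeros_like(mask)
        le[ys[side_val > 0], xs[side_val > 0]] = True
        te[ys[side_val <= 0], xs[side_val <= 0]] = True
        le_masks[cam.id] = le
        te_masks[cam.id] = te
        signs[cam.id] = float(sign)
    return le_masks, te_masks, signs


def edge_hulls(
    le_masks: dict[int, np.ndarray],
    te_masks: dict[int, np.ndarray],
    h_wing: Hull,
    carver: HullCarver,
    chord_direction: np.ndarray | None = None,
    wing_cm: np.ndarray | None = None,
    edge_dilation_px: int = 2,
) -> tuple[Hull, Hull]:
    """Carve the LE/TE pixel sets back to 3D edge hulls.

    Each edge is carved across its usable cameras and restricted to a
    one-voxel-dilated shell of the wing hull.  The one-pixel-thin boundary
    masks are dilated by ``edge_dilation_px`` before carving: the exact
    intersection of thin curves from different views is near-empty, and the
    shell restriction keeps the dilated carve tight to the wing surface.
    Voxels claimed by both edges are resolved by the sign of their offset
    from the wing CM along the chord direction (LE side positive).
    """
    grid = carver.grid
    if len(le_masks) < 2 or len(te_masks) < 2:
        warnings.warn("fewer than two usable views: edge hulls empty")
        empty = Hull(grid, np.empty(0, np.int64))
        return empty, empty
    # one-voxel-dilated shell of the wing hull (dense on its bounding box)
    idx = h_wing.indices
    lo = idx.min(axis=0) - 1
    hi = idx.max(axis=0) + 2
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, grid.dims)
    sub = np.zeros(hi - lo, dtype=bool)
    sub[tuple((idx - lo).T)] = True
    sub = binary_dilation(sub, iterations=1)
    shell_idx = np.argwhere(sub) + lo
    shell_flat = grid.flat(shell_idx)
    shell_flat.sort()

    if edge_dilation_px > 0:
        le_masks = {
            cid: binary_dilation(m, iterations=edge_dilation_px)
            for cid, m in le_masks.items()
        }
        te_masks = {
            cid: binary_dilation(m, iterations=edge_dilation_px)
            for cid, m in te_masks.items()
        }
    le_flat = carver.carve_flat(le_masks, candidates=shell_flat)
    te_flat = carver.carve_flat(te_masks, candidates=shell_flat)
    both = np.intersect1d(le_flat, te_flat)
    if both.size and chord_direction is not None and wing_cm is not None:
        side = (grid.voxel_centers(grid.unflat(both)) - wing_cm) @ np.asarray(
            chord_direction, float
        )
        le_drop = both[side <= 0]
        te_drop = both[side > 0]
        le_flat = np.setdiff1d(le_flat, le_drop)
        te_flat = np.setdiff1d(te_flat, te_drop)
    if le_flat.size == 0 or te_flat.size == 0:
        warnings.warn("an edge hull came out empty")
    return Hull(grid, le_flat), Hull(grid, te_flat)


# ---------------------------------------------------------------------------
# deformation and wing plane
# ---------------------------------------------------------------------------

def _edge_endpoint(
    pts: np.ndarray, axis: np.ndarray, slab: float, outward: float
) -> np.ndarray:
    """Mean of the extreme slab of ``pts`` along ``outward * axis``.

    The visual hull of a thin plate is pinched exactly at the plate's edge
    points (every camera's back-projected silhouette band is bounded by
    rays through them), so the extreme voxels of an edge band along the
    chord axis localize the true edge; the band's centroid does not — the
    band spreads inward (mask dilation plus hull wedge), displacing and
    tilting the mean.
    """
    d = outward * (pts @ axis)
    keep = d >= d.max() - slab
    return pts[keep].mean(axis=0)


def local_chords(
    h_le: Hull,
    h_te: Hull,
    origin: np.ndarray,
    s: np.ndarray,
    chord_frame: tuple[np.ndarray, np.ndarray] | None = None,
    n_sections: int = 5,
    chord_axis: np.ndarray | None = None,
    slab_pitches: float = 1.2,
    h_wing: Hull | None = None,
    band_pitches: float = 2.5,
) -> list[tuple[float, np.ndarray, float]]:
    """Local chord vectors (and pitch angles) in spanwise sections.

    The span axis is divided into ``n_sections`` equal radial bins between
    the innermost and outermost edge voxel (measured along ``s`` from
    ``origin``).  Per bin the chord runs from the trailing-edge to the
    leading-edge boundary voxels.  With ``h_wing`` and ``chord_axis``
    given, the endpoints are pinch extremes of the wing hull's bin
    cross-section: the section is restricted to a ``band_pitches`` slab
    around its own local plane (so a twisted wing keeps its local
    geometry) and the chord axis is re-estimated per bin (3 fixed-point
    iterations) so spanwise twist is not compressed toward a global
    direction.  Without ``h_wing`` the edge-band centroids (or their
    ``chord_axis`` extreme slabs) are used.

    The reported station is the *measured endpoints'* spanwise position as
    a fraction of the binned range — the extreme voxels concentrate where
    the chord is locally widest, which need not be the bin center, and
    using the bin center would distort spanwise profiles.

    With ``chord_frame=(c0, w)`` (the stroke-plane psi reference) the
    local pitch angle ``psi_k`` is returned, else NaN.  Bins with too few
    voxels are skipped.  Returns ``(station, unit_chord, psi_k_deg)``
    tuples ordered root to tip.
    """
    if len(h_le) == 0 or len(h_te) == 0:
        raise ValueError("both edge hulls must be non-empty")
    origin = np.asarray(origin, float)
    s = unit(np.asarray(s, float))
    grid = h_le.grid
    slab = slab_pitches * grid.pitch
    p_le = h_le.points
    p_te = h_te.points
    d_le = (p_le - origin) @ s
    d_te = (p_te - origin) @ s
    lo = min(d_le.min(), d_te.min())
    hi = max(d_le.max(), d_te.max())
    if hi - lo < 1e-12:
        raise ValueError("degenerate span extent")
    edges = np.linspace(lo, hi, n_sections + 1)
    axis0 = (unit(np.asarray(chord_axis, float))
             if chord_axis is not None else None)
    if h_wing is not None:
        p_w = h_wing.points
        d_w = (p_w - origin) @ s
    out = []
    for k in range(n_sections):
        le_pt = te_pt = None
        if h_wing is not None and axis0 is not None:
            m = (d_w >= edges[k]) & (d_w <= edges[k + 1])
            q = p_w[m]
            if len(q) >= 8:
                cmq = q.mean(0)
                _, _, vt = np.linalg.svd(q - cmq, full_matrices=False)
                nloc = vt[-1]
                q = q[np.abs((q - cmq) @ nloc) <= band_pitches * grid.pitch]
            if len(q) >= 8:
                ax = axis0
                for _ in range(3):
                    dc = q @ ax
                    le_pt = q[dc >= dc.max() - slab].mean(0)
                    te_pt = q[dc <= dc.min() + slab].mean(0)
                    ch = le_pt - te_pt
                    ch = ch - float(ch @ s) * s
                    nrm = np.linalg.norm(ch)
                    if nrm < 1e-12:
                        le_pt = None
                        break
                    ch = ch / nrm
                    if float(ch @ ax) < 0:
                        ch = -ch
                    ax = ch
        if le_pt is None:
            in_le = (d_le >= edges[k]) & (d_le <= edges[k + 1])
            in_te = (d_te >= edges[k]) & (d_te <= edges[k + 1])
            if not (in_le.any() and in_te.any()):
                continue
            if axis0 is not None:
                le_pt = _edge_endpoint(p_le[in_le], axis0, slab, +1.0)
                te_pt = _edge_endpoint(p_te[in_te], axis0, slab, -1.0)
            else:
                le_pt = p_le[in_le].mean(0)
                te_pt = p_te[in_te].mean(0)
        ch = le_pt - te_pt
        nrm = np.linalg.norm(ch)
        if nrm < 1e-12:
            continue
        ch = ch / nrm
        station = float(
            ((0.5 * (le_pt + te_pt) - origin) @ s - lo) / (hi - lo))
        if chord_frame is not None:
            c0, w = chord_frame
            psi_k = float(np.rad2deg(np.arctan2(ch @ w, ch @ c0)))
        else:
            psi_k = np.nan
        out.append((station, ch, psi_k))
    return out


def refine_span_chord(
    h_wing: Hull,
    origin: np.ndarray,
    s: np.ndarray,
    c_init: np.ndarray,
    n_bins: int = 10,
    band_pitches: float = 3.0,
    slab_pitches: float = 1.2,
    station_range: tuple[float, float] = (0.20, 0.85),
    n_iter: int = 3,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Refine the span and chord directions by wing-plane-filtered pinch
    extraction on the wing hull.

    The hull of a thin plate is pinched at the plate's edges (every
    camera's back-projected silhouette band is bounded by rays through
    them), so per spanwise bin the extreme voxel slabs along the chord axis
    localize the true LE/TE.  Ghost voxels (seen as wing in one view and
    as body/other wing elsewhere) break this, so the hull is first
    restricted to a ``band_pitches`` slab around the least-squares wing
    plane.  The per-bin LE/TE midpoints lie on the wing's mid-chord line,
    whose principal axis re-anchors the span free of the chordwise
    centroid bias of the voxel-strip stage; the chord is the weighted mean
    of per-bin endpoint differences over the mid-span stations
    (``station_range``), orthogonalized against the refined span.

    Returns ``(s_refined, c_refined, diag)``; ``diag`` carries
    ``n_bins_used`` and ``midline_rms_pitches`` (rms residual of the
    mid-chord points about their fitted line).
    """
    origin = np.asarray(origin, float)
    s_ref = unit(np.asarray(s, float))
    c_ref = unit(np.asarray(c_init, float))
    grid = h_wing.grid
    pts = h_wing.points
    band = band_pitches * grid.pitch
    slab = slab_pitches * grid.pitch
    midline_rms = np.nan
    n_used = 0
    for _ in range(n_iter):
        # wing plane: refit on the voxels inside the current band
        normal = unit(np.cross(s_ref, c_ref))
        cm = pts.mean(axis=0)
        for _ in range(2):
            keep = np.abs((pts - cm) @ normal) <= band
            if keep.sum() < 30:
                raise ValueError("too few voxels near the wing plane")
            cm = pts[keep].mean(axis=0)
            _, _, vt = np.linalg.svd(pts[keep] - cm, full_matrices=False)
            normal = vt[-1]
        in_plane = pts[np.abs((pts - cm) @ normal) <= band]
        ds = (in_plane - origin) @ s_ref
        lo, hi = ds.min(), ds.max()
        if hi - lo < 1e-12:
            raise ValueError("degenerate span extent")
        edges = np.linspace(lo, hi, n_bins + 1)
        mids, chords, weights = [], [], []
        for k in range(n_bins):
            m = (ds >= edges[k]) & (ds <= edges[k + 1])
            if m.sum() < 4:
                continue
            q = in_plane[m]
            le_pt = _edge_endpoint(q, c_ref, slab, +1.0)
            te_pt = _edge_endpoint(q, c_ref, slab, -1.0)
            st = (0.5 * (edges[k] + edges[k + 1]) - lo) / (hi - lo)
            mids.append(0.5 * (le_pt + te_pt))
            if station_range[0] <= st <= station_range[1]:
                chords.append(le_pt - te_pt)
                weights.append(float(m.sum()))
        if len(mids) < max(2, n_bins // 2) or not chords:
            raise ValueError("too few usable spanwise bins")
        mids = np.asarray(mids)
        mean_mid = mids.mean(axis=0)
        _, _, vt = np.linalg.svd(mids - mean_mid)
        s_new = vt[0]
        if float(s_new @ s_ref) < 0:
            s_new = -s_new
        s_ref = s_new
        resid = (mids - mean_mid) - np.outer((mids - mean_mid) @ s_ref, s_ref)
        midline_rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
        n_used = len(mids)
        c_sum = np.average(np.asarray(chords), axis=0, weights=weights)
        c_sum = c_sum - float(c_sum @ s_ref) * s_ref
        if np.linalg.norm(c_sum) < 1e-12:
            raise ValueError("degenerate refined chord")
        if float(c_sum @ c_ref) < 0:
            c_sum = -c_sum
        c_ref = unit(c_sum)
    diag = {
        "n_bins_used": n_used,
        "midline_rms_pitches": midline_rms / grid.pitch,
    }
    return s_ref, c_ref, diag


def wing_plane_and_final_chord(
    h_le: Hull, h_te: Hull, s: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares wing plane through the edge voxels and the final chord.

    The plane normal is the smallest principal axis of LE union TE; the final
    chord is the mean-LE-minus-mean-TE vector projected onto the plane and
    orthogonalized against the span (so ``c . s = 0`` exactly).

    Returns ``(plane_normal, chord, rms_residual_m)``.
    """
    if len(h_le) == 0 or len(h_te) == 0:
        raise ValueError("both edge hulls must be non-empty")
    pts = np.vstack([h_le.points, h_te.points])
    cm = pts.mean(axis=0)
    u, sv, vt = np.linalg.svd(pts - cm, full_matrices=False)
    if sv[1] < 1e-12:
        raise np.linalg.LinAlgError("rank-deficient edge geometry")
    normal = vt[-1]
    rms = float(np.sqrt(np.mean(((pts - cm) @ normal) ** 2)))
    s = unit(np.asarray(s, float))
    raw = h_le.points.mean(0) - h_te.points.mean(0)
    c = raw - float(raw @ normal) * normal  # into the plane
    c = c - float(c @ s) * s  # exactly perpendicular to the span
    nrm = np.linalg.norm(c)
    if nrm < 1e-12:
        raise np.linalg.LinAlgError("chord degenerate after projection")
    return normal, c / nrm, rms


# ---------------------------------------------------------------------------
# ladder orchestration for one wing, one frame
# ---------------------------------------------------------------------------

def analyze_wing(
    h_wing: Hull,
    side: int,
    r_cm_b: np.ndarray,
    wing_length: float,
    rig: CameraRig,
    carver: HullCarver,
    chord_frame: tuple[np.ndarray, np.ndarray] | None = None,
    tip_velocity: np.ndarray | None = None,
    prev: WingState | None = None,
    n_sections: int = 5,
    seed: int = 0,
    chord_init: np.ndarray | None = None,
) -> WingState:
    """Run the full refinement ladder on one wing hull.

    ``chord_frame`` is the stroke-plane psi reference (from kinematics);
    ``tip_velocity`` disambiguates the LE side (held from ``prev`` during
    stroke reversal).  ``chord_init`` seeds the pinch refinement's chord
    axis (typically the previous frame's chord — the iteration needs a
    starting axis within ~45 deg, and near stroke reversal the same-frame
    edge chord can be contaminated by the other wing).  Never raises for
    degradable stages: failures are recorded in ``WingState.flags`` and
    later stages are skipped.
    """
    flags: set[str] = set()
    strip, widened = wing_strip(h_wing, r_cm_b, wing_length)
    if widened:
        flags.add("strip_widened")
    cm_w, tip, s, tip_flags = estimate_span_tip(h_wing, strip, r_cm_b)
    flags |= tip_flags
    if "span_undefined" in flags:
        return WingState(
            side=side, cm=cm_w, tip=tip, span=s, chord=np.full(3, np.nan),
            wing_length=wing_length, hull=h_wing, flags=flags,
        )
    orient = tip_velocity
    if orient is None and prev is not None and np.all(np.isfinite(prev.chord)):
        orient = prev.chord
    try:
        c, cflags = estimate_chord_initial(strip, s, orient_toward=orient,
                                           seed=seed)
        flags |= cflags
    except (_ChordDeferred, ValueError):
        flags.add("chord_deferred")
        c = np.full(3, np.nan)

    # refinement pass: re-cut the strip perpendicular to the updated span
    d_along = (h_wing.points - r_cm_b) @ s
    lo, hi = STRIP_BOUNDS
    sel = (d_along >= lo * wing_length) & (d_along <= hi * wing_length)
    if sel.any():
        strip2 = Hull(h_wing.grid, h_wing.flat_indices[sel], _sorted=True)
        cm_w, tip, s, tf = estimate_span_tip(h_wing, strip2, r_cm_b)
        flags |= tf
        try:
            c, cflags = estimate_chord_initial(
                strip2, s, orient_toward=orient if orient is not None else
                (c if np.all(np.isfinite(c)) else None), seed=seed,
            )
            flags |= cflags
            flags.discard("chord_deferred")
        except (_ChordDeferred, ValueError):
            pass

    state = WingState(
        side=side, cm=cm_w, tip=tip, span=s, chord=c,
        wing_length=wing_length, hull=h_wing, flags=flags,
    )

    # reprojection, LE/TE, deformation, wing plane
    reproj = reproject_wing(h_wing, rig, carver=carver)
    prev_signs = getattr(prev, "_le_signs", None) if prev is not None else None
    le_masks, te_masks, signs = extract_le_te(
        reproj, rig, cm_w, tip, tip_velocity, prev_le_sign=prev_signs
    )
    state._le_signs = signs  # type: ignore[attr-defined]
    state.velocity_oriented = tip_velocity is not None and bool(
        np.linalg.norm(tip_velocity) > 0
    )
    if len(le_masks) < 2:
        flags.add("edges_unavailable")
        return state
    chord_dir = c if np.all(np.isfinite(c)) else None
    h_le, h_te = edge_hulls(
        le_masks, te_masks, h_wing, carver,
        chord_direction=chord_dir, wing_cm=cm_w,
    )
    if len(h_le) == 0 or len(h_te) == 0:
        flags.add("edges_unavailable")
        return state
    state.le_hull, state.te_hull = h_le, h_te
    try:
        # the LE/TE labels carry the orientation (mean LE - mean TE); do not
        # re-align to the k-means chord, whose sign is arbitrary on the
        # first frames
        normal, c_final, rms = wing_plane_and_final_chord(h_le, h_te, s)
        state.plane_normal = normal
        state.plane_rms = rms
        state.chord = c_final
    except np.linalg.LinAlgError:
        flags.add("plane_fit_failed")
        c_final = None
    try:
        # plane-filtered pinch refinement: per-bin chordwise extreme voxels
        # of the (wing-plane-restricted) hull localize the true LE/TE; the
        # mid-chord line re-anchors the span.  Accepted only when consistent
        # with the coarse stage — near stroke reversal the hull can be
        # contaminated by the other wing.
        if chord_init is not None and np.all(np.isfinite(chord_init)):
            c_seed = np.asarray(chord_init, float)
        elif c_final is not None:
            c_seed = c_final
        elif np.all(np.isfinite(c)):
            c_seed = c
        else:
            c_seed = np.array([1.0, 0.0, 0.0])
        s_ref, c_ref, diag = refine_span_chord(h_wing, r_cm_b, s, c_seed)
        span_shift = np.rad2deg(np.arccos(np.clip(abs(s_ref @ s), 0, 1)))
        state.midline_rms_pitches = diag["midline_rms_pitches"]
        if (span_shift <= 15.0
                and diag["midline_rms_pitches"] <= MIDLINE_RMS_MAX_PITCHES):
            state.span = s_ref
            state.chord = c_ref
            s = s_ref
        else:
            flags.add("edge_refine_rejected")
    except ValueError:
        flags.add("edge_refine_failed")
    try:
        state.local_chords = local_chords(
            h_le, h_te, r_cm_b, s, chord_frame=chord_frame,
            n_sections=n_sections,
            chord_axis=state.chord if np.all(np.isfinite(state.chord)) else None,
            h_wing=h_wing,
        )
    except ValueError:
        flags.add("deformation_unavailable")
    return state
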