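"""Voxel grids and visual-hull reconstruction.

A silhouette hull ("visual hull") is carved from a set of synchronized
binary views: a voxel belongs to the hull iff its projection lands on a
foreground pixel in *every* camera.  The hull is always a superset of the
true object, which this module exploits to recover occluded wing voxels:

* the *body hull* carves the body-only masks in all views;
* an *expanded wing hull* carves the wing-``i``-only mask in one view
  together with the full-fly masks in the remaining views, so a wing that is
  occluded in some views still contributes voxels;
* the *expanded body hull* (majority rule) keeps voxels present in at least
  two of the four single-view expanded body hulls;
* the *combined wing hull* is the union of the eight expanded wing hulls
  minus the expanded body hull, and is split into the two wings by k-means
  clustering of voxel coordinates.

Voxels whose projection falls outside a camera's image are treated as not
seen by that camera and are excluded (hulls stay inside the covisible
volume).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .cameras import CameraRig, project_point, round_pixels, triangulate_point


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice: ``origin`` is the center of voxel (0,0,0),
    ``pitch`` the cubic edge length (m), ``dims`` the (nx, ny, nz) counts."""

    origin: tuple[float, float, float]
    pitch: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def all_indices(self) -> np.ndarray:
        nx, ny, nz = self.dims
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        return np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices))
        return np.asarray(self.origin) + idx * self.pitch

    def flat(self, indices: np.ndarray) -> np.ndarray:
        """(N, 3) indices -> flat int64 indices (C order)."""
        idx = np.atleast_2d(np.asarray(indices)).astype(np.int64)
        _, ny, nz = self.dims
        return (idx[:, 0] * ny + idx[:, 1]) * nz + idx[:, 2]

    def unflat(self, flat: np.ndarray) -> np.ndarray:
        _, ny, nz = self.dims
        flat = np.asarray(flat, dtype=np.int64)
        k = flat % nz
        j = (flat // nz) % ny
        i = flat // (nz * ny)
        return np.column_stack([i, j, k])

    def point_to_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index for lab-frame point(s); may fall outside dims."""
        pts = np.atleast_2d(np.asarray(points, float))
        return np.rint((pts - np.asarray(self.origin)) / self.pitch).astype(
            np.int64
        )


class Hull:
    """A voxel set on a :class:`VoxelGrid` (set and membership views agree)."""

    def __init__(
        self, grid: VoxelGrid, flat_indices: np.ndarray, *, _sorted: bool = False
    ):
        self.grid = grid
        flat = np.asarray(flat_indices, dtype=np.int64)
        if not _sorted:
            flat = np.unique(flat)
        if flat.size and (flat[0] < 0 or flat[-1] >= grid.n_voxels):
            raise ValueError("voxel indices outside grid")
        self.flat_indices = flat

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_indices(cls, grid: VoxelGrid, indices: np.ndarray) -> "Hull":
        indices = np.asarray(indices)
        if indices.size == 0:
            return cls(grid, np.empty(0, dtype=np.int64))
        return cls(grid, grid.flat(indices))

    @classmethod
    def from_mask(cls, grid: VoxelGrid, mask: np.ndarray) -> "Hull":
        return cls(grid, np.flatnonzero(np.asarray(mask).ravel()))

    # -- views --------------------------------------------------------------
    @property
    def indices(self) -> np.ndarray:
        """(N, 3) integer voxel indices."""
        return self.grid.unflat(self.flat_indices)

    @property
    def points(self) -> np.ndarray:
        """(N, 3) lab-frame voxel-center coordinates (m)."""
        return self.grid.voxel_centers(self.indices)

    def contains(self, indices: np.ndarray) -> np.ndarray:
        """Membership function on the grid (functional hull notation)."""
        return np.isin(self.grid.flat(indices), self.flat_indices)

    def as_mask(self) -> np.ndarray:
        m = np.zeros(self.grid.n_voxels, dtype=bool)
        m[self.flat_indices] = True
        return m.reshape(self.grid.dims)

    def __len__(self) -> int:
        return int(self.flat_indices.size)

    @property
    def volume(self) -> float:
        """Total voxel volume (m^3)."""
        return len(self) * self.grid.pitch**3

    def centroid(self) -> np.ndarray:
        if len(self) == 0:
            raise ValueError("empty hull has no centroid")
        return self.points.mean(axis=0)

    # -- set algebra --------------------------------------------------------
    def _check(self, other: "Hull") -> None:
        if other.grid != self.grid:
            raise ValueError("hulls live on different grids")

    def union(self, other: "Hull") -> "Hull":
        self._check(other)
        return Hull(self.grid, np.union1d(self.flat_indices, other.flat_indices))

    def intersection(self, other: "Hull") -> "Hull":
        self._check(other)
        return Hull(
            self.grid, np.intersect1d(self.flat_indices, other.flat_indices)
        )

    def difference(self, other: "Hull") -> "Hull":
        self._check(other)
        return Hull(
            self.grid,
            np.setdiff1d(self.flat_indices, other.flat_indices),
        )

    __or__ = union
    __and__ = intersection
    __sub__ = difference

    def issubset(self, other: "Hull") -> bool:
        self._check(other)
        return np.isin(self.flat_indices, other.flat_indices).all()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Hull)
            and other.grid == self.grid
            and np.array_equal(other.flat_indices, self.flat_indices)
        )


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

def build_voxel_grid(
    body_cm_2d: dict[int, np.ndarray],
    rig: CameraRig,
    wing_length: float,
    extent_in_wing_lengths: float = 2.8,
    pitch: float = 40e-6,
    residual_warn_px: float = 2.0,
) -> tuple[VoxelGrid, np.ndarray]:
    """Center a cubic voxel grid on the triangulated 3D body CM.

    ``body_cm_2d`` maps camera id to the 2D body CM in that view; at least
    two views are required.  The cube side is
    ``extent_in_wing_lengths * wing_length``.  Returns (grid, cm_3d).
    """
    cams = [c for c in rig if c.id in body_cm_2d]
    if len(cams) < 2:
        raise ValueError("body CM must be visible in at least two cameras")
    cm3d, rms = triangulate_point(cams, [body_cm_2d[c.id] for c in cams])
    if rms > residual_warn_px:
        warnings.warn(
            f"body-CM triangulation residual {rms:.2f} px exceeds "
            f"{residual_warn_px} px"
        )
    side = extent_in_wing_lengths * wing_length
    n = int(round(side / pitch))
    # snap the origin to the pitch lattice so identical fly positions reuse
    # cached voxel projections
    lo = np.round((cm3d - side / 2.0) / pitch) * pitch
    return VoxelGrid(origin=tuple(lo), pitch=pitch, dims=(n, n, n)), cm3d


# ---------------------------------------------------------------------------
# carving
# ---------------------------------------------------------------------------

class HullCarver:
    """Carver with cached voxel-grid projections for one (grid, rig) pair.

    Projecting a few million voxel centers dominates carving cost; the
    projections depend only on the grid and rig, so they are computed once
    and every hull of a frame (body, expanded, ...) reuses them.
    """

    def __init__(self, grid: VoxelGrid, rig: CameraRig):
        self.grid = grid
        self.rig = rig
        self._pix: dict[int, np.ndarray] = {}  # cam id -> flat pixel index
        self._ok: dict[int, np.ndarray] = {}  # cam id -> in-image flag
        nx, ny, nz = grid.dims
        centers_w_ones = None
        for cam in rig:
            # chunk over x-slabs to bound temporary memory
            pix = np.empty(grid.n_voxels, dtype=np.int32)
            ok = np.empty(grid.n_voxels, dtype=bool)
            w, h = cam.image_size
            chunk = max(1, int(2e6 // (ny * nz)))
            for i0 in range(0, nx, chunk):
                i1 = min(nx, i0 + chunk)
                ii, jj, kk = np.meshgrid(
                    np.arange(i0, i1),
                    np.arange(ny),
                    np.arange(nz),
                    indexing="ij",
                )
                idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
                px = round_pixels(
                    project_point(cam, grid.voxel_centers(idx))
                )
                sl = slice(i0 * ny * nz, i1 * ny * nz)
                good = (
                    (px[:, 0] >= 0)
                    & (px[:, 0] < w)
                    & (px[:, 1] >= 0)
                    & (px[:, 1] < h)
                )
                ok[sl] = good
                flat = px[:, 1].clip(0, h - 1) * w + px[:, 0].clip(0, w - 1)
                pix[sl] = flat.astype(np.int32)
            self._pix[cam.id] = pix
            self._ok[cam.id] = ok

    def carve_flat(
        self,
        masks: dict[int, np.ndarray],
        candidates: np.ndarray | None = None,
    ) -> np.ndarray:
        """Flat indices of voxels whose pixel is foreground in every mask.

        ``masks`` maps camera id -> 2D bool mask (H, W).  ``candidates``
        optionally restricts the search to a flat-index subset.
        """
        if candidates is None:
            survivors = None
        else:
            survivors = np.asarray(candidates, dtype=np.int64)
        for cam_id, mask in masks.items():
            flat_mask = np.asarray(mask, dtype=bool).ravel()
            pix = self._pix[cam_id]
            ok = self._ok[cam_id]
            if survivors is None:
                keep = ok & flat_mask[pix]
                survivors = np.flatnonzero(keep)
            else:
                keep = ok[survivors] & flat_mask[pix[survivors]]
                survivors = survivors[keep]
            if survivors.size == 0:
                break
        return survivors if survivors is not None else np.empty(0, np.int64)

    def seen_by(
        self, cam_id: int, mask: np.ndarray, candidates: np.ndarray
    ) -> np.ndarray:
        """Bool array: which candidate voxels project onto ``mask`` pixels."""
        flat_mask = np.asarray(mask, dtype=bool).ravel()
        c = np.asarray(candidates, dtype=np.int64)
        return self._ok[cam_id][c] & flat_mask[self._pix[cam_id][c]]

    def carve(
        self, masks: dict[int, np.ndarray], candidates: np.ndarray | None = None
    ) -> Hull:
        flat = self.carve_flat(masks, candidates)
        if flat.size == 0:
            warnings.warn("carved hull is empty")
        return Hull(self.grid, flat)


def carve(grid: VoxelGrid, masks: dict[int, np.ndarray], rig: CameraRig) -> Hull:
    """One-shot carve: voxel kept iff foreground in every camera's mask."""
    return HullCarver(grid, rig).carve(masks)


def body_hull(
    grid: VoxelGrid,
    body_masks: dict[int, np.ndarray],
    rig: CameraRig,
    carver: HullCarver | None = None,
) -> Hull:
    """Carve the body-only masks of all views."""
    carver = carver or HullCarver(grid, rig)
    return carver.carve(body_masks)


def expanded_wing_hull(
    wing_mask_j: np.ndarray,
    cam_j: int,
    full_masks: dict[int, np.ndarray],
    grid: VoxelGrid,
    rig: CameraRig,
    carver: HullCarver | None = None,
) -> Hull:
    """Carve the wing-only mask in view ``cam_j`` with full-fly masks in the
    remaining views (single-view expanded wing hull)."""
    carver = carver or HullCarver(grid, rig)
    masks = {cid: m for cid, m in full_masks.items() if cid != cam_j}
    masks[cam_j] = wing_mask_j
    if not np.any(wing_mask_j):
        warnings.warn(f"wing occluded in view {cam_j}: empty expanded hull")
        return Hull(grid, np.empty(0, np.int64))
    return carver.carve(masks)


def expanded_body_hull(
    body_mask_j: np.ndarray,
    cam_j: int,
    full_masks: dict[int, np.ndarray],
    grid: VoxelGrid,
    rig: CameraRig,
    carver: HullCarver | None = None,
) -> Hull:
    """Carve the body-only mask in view ``cam_j`` with full-fly masks in the
    remaining views (single-view expanded body hull)."""
    carver = carver or HullCarver(grid, rig)
    masks = {cid: m for cid, m in full_masks.items() if cid != cam_j}
    masks[cam_j] = body_mask_j
    return carver.carve(masks)


def majority_body_hull(expanded_body_hulls: Sequence[Hull]) -> Hull:
    """Keep voxels present in at least two of the expanded body hulls."""
    hulls = list(expanded_body_hulls)
    grid = hulls[0].grid
    allv = np.concatenate([h.flat_indices for h in hulls])
    vals, counts = np.unique(allv, return_counts=True)
    return Hull(grid, vals[counts >= 2])


def combined_wing_hull(
    expanded_wing_hulls: Sequence[Hull], expanded_body: Hull
) -> Hull:
    """Union of the eight expanded wing hulls minus the expanded body hull."""
    hulls = list(expanded_wing_hulls)
    grid = hulls[0].grid
    union = np.unique(np.concatenate([h.flat_indices for h in hulls]))
    out = Hull(grid, np.setdiff1d(union, expanded_body.flat_indices))
    if len(out) == 0:
        warnings.warn("combined wing hull is empty: frame unresolvable")
    return out


@dataclass
class HullBundle:
    """All hulls reconstructed for one frame."""

    body: Hull
    expanded_body: dict[int, Hull]  # camera id -> single-view expanded hull
    expanded_wings: dict[tuple[int, int], Hull]  # (wing index, camera id)
    majority_body: Hull
    two_wings: Hull
    wing_left: Hull | None = None
    wing_right: Hull | None = None
    wings_merged_3d: bool = False
    merged_views: tuple[int, ...] = ()


def wing_view_components(
    wing_mask: np.ndarray, max_components: int = 2
) -> tuple[list[np.ndarray], bool]:
    """Split one view's wing mask into its (up to 2) largest connected
    components.  Returns ``(component_masks, merged)`` where ``merged`` is
    True when the wings form a single connected component in this view."""
    from skimage.measure import label

    lab = label(wing_mask, connectivity=2)
    n = lab.max()
    if n == 0:
        return [], False
    sizes = np.bincount(lab.ravel())[1:]
    order = np.argsort(sizes)[::-1][:max_components] + 1
    comps = [lab == k for k in order]
    return comps, len(comps) == 1


def reconstruct_frame(
    carver: HullCarver,
    full_masks: dict[int, np.ndarray],
    body_masks: dict[int, np.ndarray],
    wing_masks: dict[int, np.ndarray],
    prev_wing_cms: tuple[np.ndarray, np.ndarray] | None = None,
    body_y_axis: np.ndarray | None = None,
    body_cm: np.ndarray | None = None,
    seed: int = 0,
) -> HullBundle:
    """Reconstruct every hull of one frame, sharing cached projections.

    Because every part mask is a subset of its view's full-fly mask, every
    expanded hull is a subset of the full-silhouette hull; all part hulls
    are therefore evaluated only on the full hull's voxels, which is
    algebraically identical to carving them on the whole grid.
    """
    grid = carver.grid
    cand = carver.carve_flat(full_masks)
    cam_ids = sorted(full_masks)

    body_seen = {
        cid: carver.seen_by(cid, body_masks[cid], cand) for cid in cam_ids
    }
    body_all = np.logical_and.reduce([body_seen[c] for c in cam_ids])
    h_body = Hull(grid, cand[body_all], _sorted=True)

    expanded_body = {
        cid: Hull(grid, cand[body_seen[cid]], _sorted=True) for cid in cam_ids
    }
    body_count = np.sum([body_seen[c] for c in cam_ids], axis=0)
    h_majority = Hull(grid, cand[body_count >= 2], _sorted=True)

    expanded_wings: dict[tuple[int, int], Hull] = {}
    merged_views = []
    union_seen = np.zeros(len(cand), dtype=bool)
    for cid in cam_ids:
        comps, merged = wing_view_components(wing_masks[cid])
        if merged:
            merged_views.append(cid)
        if not comps:
            warnings.warn(f"no wing pixels in view {cid}: wings fully occluded")
            empty = Hull(grid, np.empty(0, np.int64))
            expanded_wings[(1, cid)] = empty
            expanded_wings[(2, cid)] = empty
            continue
        seen = [carver.seen_by(cid, c, cand) for c in comps]
        if len(seen) == 1:
            seen.append(seen[0])  # merged-component rule: both wings share it
        for i in (1, 2):
            expanded_wings[(i, cid)] = Hull(grid, cand[seen[i - 1]], _sorted=True)
            union_seen |= seen[i - 1]

    two = union_seen & ~(body_count >= 2)
    h_two = Hull(grid, cand[two], _sorted=True)
    bundle = HullBundle(
        body=h_body,
        expanded_body=expanded_body,
        expanded_wings=expanded_wings,
        majority_body=h_majority,
        two_wings=h_two,
        merged_views=tuple(merged_views),
    )
    if len(h_two) == 0:
        warnings.warn("combined wing hull empty: frame unresolvable")
        return bundle
    if prev_wing_cms is not None or body_y_axis is not None:
        left, right, merged3d = split_wings(
            h_two,
            prev_wing_cms=prev_wing_cms,
            body_y_axis=body_y_axis,
            body_cm=body_cm,
            seed=seed,
        )
        bundle.wing_left = left
        bundle.wing_right = right
        bundle.wings_merged_3d = merged3d
    return bundle


def split_wings(
    two_wing_hull: Hull,
    prev_wing_cms: tuple[np.ndarray, np.ndarray] | None = None,
    body_y_axis: np.ndarray | None = None,
    body_cm: np.ndarray | None = None,
    seed: int = 0,
    min_separation_pitches: float = 2.0,
) -> tuple[Hull, Hull, bool]:
    """Split the combined two-wing hull into (left, right) wing hulls.

    k=2 k-means on voxel coordinates.  Cluster-to-wing identity is assigned
    by nearest previous-frame wing CM when given, otherwise by the sign of
    the projection on the body y-axis (left wing positive).  Returns
    ``(left, right, merged)`` where ``merged`` flags clusters whose CM
    separation is below ``min_separation_pitches`` voxel pitches.
    """
    if len(two_wing_hull) == 0:
        raise ValueError("cannot split an empty hull")
    pts = two_wing_hull.points
    if prev_wing_cms is not None:
        init = np.vstack(prev_wing_cms)
    elif body_y_axis is not None:
        y = np.asarray(body_y_axis, float)
        proj = pts @ y
        init = np.vstack([pts[np.argmax(proj)], pts[np.argmin(proj)]])
    else:
        raise ValueError("need prev_wing_cms or body_y_axis to seed the split")
    if np.linalg.norm(init[0] - init[1]) < 1e-12:
        init = init + np.array([[1e-9, 0, 0], [-1e-9, 0, 0]])
    km = KMeans(
        n_clusters=2, init=init, n_init=1, random_state=seed, max_iter=300
    ).fit(pts)
    labels = km.labels_
    flat = two_wing_hull.flat_indices
    a = Hull(two_wing_hull.grid, flat[labels == 0])
    b = Hull(two_wing_hull.grid, flat[labels == 1])
    merged = False
    sep = np.linalg.norm(km.cluster_centers_[0] - km.cluster_centers_[1])
    if len(a) == 0 or len(b) == 0 or sep < min_separation_pitches * two_wing_hull.grid.pitch:
        merged = True
        warnings.warn("wings merged in 3D: cluster separation below threshold")
    # identity assignment
    if prev_wing_cms is not None:
        ca, cb = km.cluster_centers_
        pl, pr = prev_wing_cms
        cost_keep = np.linalg.norm(ca - pl) + np.linalg.norm(cb - pr)
        cost_swap = np.linalg.norm(ca - pr) + np.linalg.norm(cb - pl)
        left, right = (a, b) if cost_keep <= cost_swap else (b, a)
    else:
        y = np.asarray(body_y_axis, float)
        ref = np.zeros(3) if body_cm is None else np.asarray(body_cm, float)
        sa = float((km.cluster_centers_[0] - ref) @ y)
        left, right = (a, b) if sa >= 0 else (b, a)
    return left, right, merged
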