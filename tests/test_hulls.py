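"""Voxel grids, carving, expanded-hull set algebra and the wing split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyhull import hulls as hl
from flyhull.cameras import make_rig, project_point, round_pixels
from flyhull.segmentation import mask_centroid
from flyhull.synthetic_fly import voxelize_posed


def brute_force_carve(grid, masks, rig):
    """Oracle: loop every voxel x camera, test the rounded projection."""
    keep = []
    for idx in grid.all_indices():
        ok = True
        for cam in rig:
            if cam.id not in masks:
                continue
            px = round_pixels(project_point(cam, grid.voxel_centers(idx)[0]))
            w, h = cam.image_size
            if not (0 <= px[0] < w and 0 <= px[1] < h):
                ok = False
                break
            if not masks[cam.id][px[1], px[0]]:
                ok = False
                break
        if ok:
            keep.append(idx)
    return hl.Hull.from_indices(
        grid, np.asarray(keep) if keep else np.empty((0, 3), int)
    )


@pytest.fixture(scope="module")
def small_grid():
    return hl.VoxelGrid(origin=(-0.9e-3, -0.9e-3, -0.9e-3), pitch=2e-4,
                        dims=(10, 10, 10))


class TestVoxelGrid:
    def test_dims_arithmetic_example(self, rig):
        """Extent 2 wing lengths of 2.5 mm at 50 um pitch gives 100^3."""
        cm2d = {c.id: project_point(c, np.zeros(3)) for c in rig}
        grid, cm3d = hl.build_voxel_grid(
            cm2d, rig, wing_length=2.5e-3, extent_in_wing_lengths=2.0,
            pitch=50e-6,
        )
        assert grid.dims == (100, 100, 100)
        assert np.allclose(cm3d, 0.0, atol=1e-9)

    def test_triangulated_cm_near_truth(self, rendered_frame, rig):
        posed, views, _, _ = rendered_frame
        cm2d = {cid: mask_centroid(v.body_mask) for cid, v in views.items()}
        grid, cm3d = hl.build_voxel_grid(cm2d, rig, wing_length=2.5e-3,
                                         pitch=30e-6)
        assert np.linalg.norm(cm3d - posed.body_center) < 2 * grid.pitch

    def test_too_few_cameras(self, rig):
        with pytest.raises(ValueError):
            hl.build_voxel_grid({1: np.array([10.0, 10.0])}, rig,
                                wing_length=2.5e-3)

    def test_flat_round_trip(self, small_grid):
        idx = np.array([[0, 0, 0], [9, 9, 9], [3, 7, 1]])
        assert np.array_equal(small_grid.unflat(small_grid.flat(idx)), idx)


class TestCarve:
    def test_all_true_masks_keep_grid(self, small_grid, rig):
        masks = {c.id: np.ones(c.image_size[::-1], bool) for c in rig}
        hull = hl.carve(small_grid, masks, rig)
        assert len(hull) == small_grid.n_voxels

    def test_one_empty_mask_empties_hull(self, small_grid, rig):
        masks = {c.id: np.ones(c.image_size[::-1], bool) for c in rig}
        masks[2] = np.zeros_like(masks[2])
        with pytest.warns(UserWarning):
            hull = hl.carve(small_grid, masks, rig)
        assert len(hull) == 0

    @settings(deadline=None, max_examples=15)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        """Carving random blob masks equals the per-voxel loop exactly."""
        rig = make_rig("hybrid4", image_size=(48, 48), pixel_pitch=120e-6)
        grid = hl.VoxelGrid(origin=(-8e-4, -8e-4, -8e-4), pitch=2e-4,
                            dims=(8, 8, 8))
        rng = np.random.default_rng(seed)
        masks = {}
        for c in rig:
            m = np.zeros((48, 48), bool)
            cx, cy = rng.integers(10, 38, 2)
            r = rng.integers(4, 14)
            yy, xx = np.mgrid[:48, :48]
            masks[c.id] = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        fast = hl.carve(grid, masks, rig)
        slow = brute_force_carve(grid, masks, rig)
        assert fast == slow

    def test_monotone_in_mask_size(self, small_grid, rig, rendered_frame):
        """Dilating any one mask never shrinks the carved hull."""
        from scipy.ndimage import binary_dilation

        _, views, _, _ = rendered_frame
        masks = {cid: v.full for cid, v in views.items()}
        base = hl.carve(small_grid, masks, rig)
        bigger = dict(masks)
        bigger[1] = binary_dilation(masks[1], iterations=2)
        grown = hl.carve(small_grid, bigger, rig)
        assert base.issubset(grown)


class TestVisualHullProperties:
    def test_superset_of_body_interior(self, rendered_frame, rig):
        """No voxel of the body interior (one-pitch margin) is lost by the
        full-silhouette carve."""
        posed, views, _, _ = rendered_frame
        cm2d = {cid: mask_centroid(v.body_mask) for cid, v in views.items()}
        grid, _ = hl.build_voxel_grid(cm2d, rig, wing_length=2.5e-3,
                                      pitch=30e-6)
        hull = hl.carve(grid, {cid: v.full for cid, v in views.items()}, rig)
        body_vox = voxelize_posed(posed, grid, parts=("body",))
        assert len(body_vox) > 1000
        assert body_vox.issubset(hull)

    def test_wing_surface_coverage(self, rendered_frame, rig):
        """The full hull covers >=90% of the wing-surface voxelization
        (exact containment is unattainable for a zero-thickness surface)."""
        posed, views, _, _ = rendered_frame
        cm2d = {cid: mask_centroid(v.body_mask) for cid, v in views.items()}
        grid, _ = hl.build_voxel_grid(cm2d, rig, wing_length=2.5e-3,
                                      pitch=30e-6)
        hull = hl.carve(grid, {cid: v.full for cid, v in views.items()}, rig)
        wings = voxelize_posed(posed, grid, margin=grid.pitch,
                               parts=("wings",))
        covered = len(wings.intersection(hull)) / len(wings)
        assert covered >= 0.9

    def test_volume_converges_from_above(self, model, rig):
        """Hull volume of the body decreases toward the true volume as the
        pitch shrinks (visual-hull superset at any resolution)."""
        from flyhull.synthetic_fly import BodyPose, WingPose, pose_model, \
            render_silhouettes

        body = BodyPose.from_angles((0, 0, 0))
        posed = pose_model(model, body, WingPose(90, 80, 0, +1),
                           WingPose(90, 80, 0, -1))  # wings up, clear body
        views = render_silhouettes(posed, rig)
        masks = {cid: v.body_mask for cid, v in views.items()}
        a, b, c = model.body_semi_axes
        true_vol = 4.0 / 3.0 * np.pi * a * b * c
        vols = []
        for pitch in (120e-6, 60e-6, 30e-6):
            n = int(3e-3 / pitch)
            grid = hl.VoxelGrid(origin=(-1.5e-3, -1.5e-3, -1.5e-3),
                                pitch=pitch, dims=(n, n, n))
            vols.append(hl.carve(grid, masks, rig).volume)
        assert vols[0] >= vols[1] >= vols[2] >= true_vol * 0.98


class TestSetAlgebra:
    def _random_hull(self, grid, rng):
        n = rng.integers(1, 60)
        return hl.Hull.from_indices(
            grid, rng.integers(0, grid.dims[0], size=(n, 3))
        )

    def test_majority_rule_membership(self, small_grid):
        """In exactly one hull -> out; in exactly two -> in."""
        h1 = hl.Hull.from_indices(small_grid, [[1, 1, 1], [2, 2, 2]])
        h2 = hl.Hull.from_indices(small_grid, [[2, 2, 2], [3, 3, 3]])
        h3 = hl.Hull.from_indices(small_grid, [[3, 3, 3]])
        h4 = hl.Hull.from_indices(small_grid, [[4, 4, 4]])
        maj = hl.majority_body_hull([h1, h2, h3, h4])
        assert maj.contains([[2, 2, 2]]).all()
        assert maj.contains([[3, 3, 3]]).all()
        assert not maj.contains([[1, 1, 1]]).any()
        assert not maj.contains([[4, 4, 4]]).any()

    def test_identical_hulls_pass_through(self, small_grid):
        h = hl.Hull.from_indices(small_grid, [[5, 5, 5], [6, 6, 6]])
        assert hl.majority_body_hull([h, h, h, h]) == h

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_majority_and_union_match_counting_oracle(self, seed):
        """Majority rule and combined-wing set algebra equal brute-force
        per-voxel counting over random hulls."""
        grid = hl.VoxelGrid(origin=(0, 0, 0), pitch=1e-4, dims=(6, 6, 6))
        rng = np.random.default_rng(seed)
        body_hulls = [self._random_hull(grid, rng) for _ in range(4)]
        wing_hulls = [self._random_hull(grid, rng) for _ in range(8)]

        maj = hl.majority_body_hull(body_hulls)
        combined = hl.combined_wing_hull(wing_hulls, maj)

        for idx in grid.all_indices():
            count = sum(h.contains([idx])[0] for h in body_hulls)
            in_maj = count >= 2
            assert maj.contains([idx])[0] == in_maj
            in_union = any(h.contains([idx])[0] for h in wing_hulls)
            assert combined.contains([idx])[0] == (in_union and not in_maj)

    def test_body_hull_subset_of_full(self, rendered_frame, rig):
        _, views, _, _ = rendered_frame
        cm2d = {cid: mask_centroid(v.body_mask) for cid, v in views.items()}
        grid, _ = hl.build_voxel_grid(cm2d, rig, wing_length=2.5e-3,
                                      pitch=40e-6)
        carver = hl.HullCarver(grid, rig)
        full = carver.carve({cid: v.full for cid, v in views.items()})
        body = carver.carve({cid: v.body_mask for cid, v in views.items()})
        assert body.issubset(full)

    def test_expanded_hull_matches_direct_carve(self, rendered_frame, rig):
        """The expanded wing hull equals a one-shot carve with the stated
        mask combination."""
        _, views, _, _ = rendered_frame
        full_masks = {cid: v.full for cid, v in views.items()}
        wing1 = views[1].wing_masks[+1] & views[1].visible_wing_mask(+1)
        cm2d = {cid: mask_centroid(v.body_mask) for cid, v in views.items()}
        grid, _ = hl.build_voxel_grid(cm2d, rig, wing_length=2.5e-3,
                                      pitch=40e-6)
        carver = hl.HullCarver(grid, rig)
        expanded = hl.expanded_wing_hull(wing1, 1, full_masks, grid, rig,
                                         carver=carver)
        direct_masks = {cid: m for cid, m in full_masks.items() if cid != 1}
        direct_masks[1] = wing1
        assert expanded == carver.carve(direct_masks)

    def test_merged_component_rule(self, rig, rendered_frame):
        """A single merged wing component in a view yields identical
        expanded hulls for both wings in that view."""
        _, views, _, _ = rendered_frame
        full_masks = {cid: v.full for cid, v in views.items()}
        body_masks = {cid: v.body_mask & v.full for cid, v in views.items()}
        # force a merged component in view 2 by joining both wings' masks
        wing_masks = {cid: full_masks[cid] & ~body_masks[cid]
                      for cid in full_masks}
        cm2d = {cid: mask_centroid(v.body_mask) for cid, v in views.items()}
        grid, cm3d = hl.build_voxel_grid(cm2d, rig, wing_length=2.5e-3,
                                         pitch=40e-6)
        carver = hl.HullCarver(grid, rig)
        from scipy.ndimage import binary_dilation

        wing_masks[2] = binary_dilation(wing_masks[2], iterations=6)
        bundle = hl.reconstruct_frame(carver, full_masks, body_masks,
                                      wing_masks)
        if 2 in bundle.merged_views:
            assert bundle.expanded_wings[(1, 2)] == bundle.expanded_wings[
                (2, 2)]


class TestSplitWings:
    def test_disjoint_blobs_split_exactly(self, small_grid):
        blob_a = [[1, 1, 1], [1, 2, 1], [2, 1, 1]]
        blob_b = [[8, 8, 8], [8, 7, 8], [7, 8, 8]]
        two = hl.Hull.from_indices(small_grid, blob_a + blob_b)
        left, right, merged = hl.split_wings(
            two, body_y_axis=np.array([0, 1.0, 0]),
            body_cm=small_grid.voxel_centers([[5, 5, 5]])[0],
        )
        assert not merged
        # the +y blob is labeled left
        got = {tuple(i) for i in right.indices}
        assert got == {tuple(b) for b in blob_a}
        assert {tuple(i) for i in left.indices} == {tuple(b) for b in blob_b}

    def test_sides_match_ground_truth(self, rendered_frame, rig):
        posed, views, f, seq = rendered_frame
        full = {cid: v.full for cid, v in views.items()}
        body = {cid: v.body_mask & v.full for cid, v in views.items()}
        wing = {cid: full[cid] & ~body[cid] for cid in full}
        cm2d = {cid: mask_centroid(v.body_mask) for cid, v in views.items()}
        grid, cm3d = hl.build_voxel_grid(cm2d, rig, wing_length=2.5e-3,
                                         pitch=40e-6)
        carver = hl.HullCarver(grid, rig)
        bundle = hl.reconstruct_frame(
            carver, full, body, wing, body_y_axis=seq.body[f].y_b,
            body_cm=cm3d,
        )
        tip_l = posed.wings[+1].hinge + 2.5e-3 * posed.wings[+1].span
        tip_r = posed.wings[-1].hinge + 2.5e-3 * posed.wings[-1].span
        assert np.linalg.norm(bundle.wing_left.centroid() - tip_l) < \
            np.linalg.norm(bundle.wing_left.centroid() - tip_r)

    def test_empty_hull_rejected(self, small_grid):
        empty = hl.Hull(small_grid, np.empty(0, np.int64))
        with pytest.raises(ValueError):
            hl.split_wings(empty, body_y_axis=np.array([0, 1.0, 0]))
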