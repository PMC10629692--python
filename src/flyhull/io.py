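"""File formats: image stacks, hull files, tables.

* Image stacks: one multi-page TIFF per camera (``cam<id>.tif``), binary
  or grayscale, frames in temporal order.
* Hulls: ``.hull.npz`` — compressed voxel-index table plus a JSON header
  describing the grid (origin, pitch, dims); optional ASCII PLY export of
  voxel centers for visualization.
* Tables (kinematics, wingbeat summaries, ground truth): plain CSV.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import tifffile

from .hulls import Hull, VoxelGrid

_CAM_RE = re.compile(r"cam(\d+)\.tiff?$")


def write_stacks(stacks: dict[int, np.ndarray], outdir) -> None:
    """Write per-camera stacks as ``cam<id>.tif`` multi-page TIFFs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cid, stack in stacks.items():
        data = np.asarray(stack)
        if data.dtype == bool:
            data = data.astype(np.uint8) * 255
        tifffile.imwrite(outdir / f"cam{cid}.tif", data, compression="zlib")


def read_stacks(indir) -> dict[int, np.ndarray]:
    """Read every ``cam<id>.tif(f)`` stack in a directory."""
    indir = Path(indir)
    out = {}
    for path in sorted(indir.iterdir()):
        m = _CAM_RE.search(path.name)
        if not m:
            continue
        out[int(m.group(1))] = tifffile.imread(path)
    if not out:
        raise FileNotFoundError(f"no cam<id>.tif stacks found in {indir}")
    return out


def write_hull(hull: Hull, path) -> None:
    """Write a hull as a compressed index table with a JSON grid header."""
    header = json.dumps(
        {
            "origin": list(hull.grid.origin),
            "pitch": hull.grid.pitch,
            "dims": list(hull.grid.dims),
        }
    )
    np.savez_compressed(
        path, header=np.frombuffer(header.encode(), dtype=np.uint8),
        flat_indices=hull.flat_indices,
    )


def read_hull(path) -> Hull:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        grid = VoxelGrid(
            origin=tuple(header["origin"]),
            pitch=float(header["pitch"]),
            dims=tuple(header["dims"]),
        )
        return Hull(grid, data["flat_indices"], _sorted=True)


def write_hull_ply(hull: Hull, path) -> None:
    """Export voxel centers as an ASCII PLY point cloud."""
    pts = hull.points
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(pts)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "end_header\n"
        )
        for x, y, z in pts:
            fh.write(f"{x:.6e} {y:.6e} {z:.6e}\n")
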