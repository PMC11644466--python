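"""Reduce binary root masks to unit-thickness skeletons in 2-D and 3-D.

Thinning is topology-preserving: connected-component counts are preserved,
the skeleton is a subset of the input foreground, and no remaining
foreground cell can be deleted without changing local topology.  2-D uses
iterative morphological thinning; 3-D uses medial-axis thinning by
simple-point deletion with directional sub-iterations (26-connected
foreground, 6-connected background).  No spur pruning is applied by
default; short terminal branches can optionally be pruned, which slightly
lowers fractal-dimension estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize

from .raster import (
    BinaryImage2D,
    BinaryVolume3D,
    VoxelGrid,
    load_binary_volume_tiff,
    load_image_png,
    save_volume_tiff,
)

__all__ = [
    "Skeleton",
    "skeletonize_2d",
    "skeletonize_3d",
    "prune_skeleton",
    "save_skeleton",
    "load_skeleton",
    "skeleton_to_csv",
]


@dataclass
class Skeleton:
    """Unit-thickness foreground raster plus per-axis physical pitch (cm).

    ``pitch_cm`` follows array-axis order: (row, col) for 2-D and
    (slice, row, col) = (z, y, x) for 3-D.
    """

    raster: np.ndarray
    pitch_cm: tuple

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.ndim not in (2, 3):
            raise ValueError("skeleton raster must be 2-D or 3-D")
        self.pitch_cm = tuple(float(p) for p in self.pitch_cm)
        if len(self.pitch_cm) != self.raster.ndim:
            raise ValueError("pitch_cm must give one spacing per raster axis")
        if min(self.pitch_cm) <= 0:
            raise ValueError("pitch must be positive")

    @property
    def dims(self) -> int:
        return self.raster.ndim


def skeletonize_2d(image: BinaryImage2D) -> Skeleton:
    """Thin a binary photograph to unit thickness (pitch carried over)."""
    pitch = (image.pitch_cm_per_px, image.pitch_cm_per_px)
    if not image.pixels.any():
        warnings.warn("empty foreground: returning an empty skeleton", stacklevel=2)
        return Skeleton(np.zeros_like(image.pixels), pitch)
    return Skeleton(_sk_skeletonize(image.pixels), pitch)


def skeletonize_3d(mask: BinaryVolume3D) -> Skeleton:
    """Thin a binary CT mask to a unit-thickness 3-D skeleton."""
    g = mask.grid
    pitch = (g.voxel_z_mm / 10.0, g.voxel_y_mm / 10.0, g.voxel_x_mm / 10.0)
    if not mask.mask.any():
        warnings.warn("empty foreground: returning an empty skeleton", stacklevel=2)
        return Skeleton(np.zeros_like(mask.mask), pitch)
    return Skeleton(_sk_skeletonize(mask.mask).astype(bool), pitch)


def _neighbor_counts(raster: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    kernel = np.ones((3,) * raster.ndim)
    return ndimage.convolve(raster.astype(np.uint8), kernel, mode="constant") - raster


def prune_skeleton(skel: Skeleton, min_branch_cells: int) -> Skeleton:
    """Iteratively remove terminal cells, up to ``min_branch_cells`` rounds.

    A crude spur filter: each round deletes cells with exactly one
    foreground neighbor (tips), so branches shorter than the given number
    of cells disappear.  Off by default in every pipeline.
    """
    raster = skel.raster.copy()
    for _ in range(int(min_branch_cells)):
        tips = raster & (_neighbor_counts(raster) == 1)
        if not tips.any():
            break
        raster &= ~tips
    return Skeleton(raster, skel.pitch_cm)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_skeleton(skel: Skeleton, path) -> None:
    """PNG for 2-D skeletons, multi-page TIFF for 3-D; pitch in a sidecar."""
    path = Path(path)
    if skel.dims == 2:
        from .raster import save_image_png

        save_image_png(BinaryImage2D(skel.raster, skel.pitch_cm[0]), path)
        with open(path.with_suffix(".meta.txt"), "w") as fh:
            fh.write(f"pitch_cm_per_px: {skel.pitch_cm[0]}\n")
            fh.write(f"pitch_cm: [{', '.join(str(p) for p in skel.pitch_cm)}]\n")
    else:
        nz, ny, nx = skel.raster.shape
        pz, py, px = skel.pitch_cm
        grid = VoxelGrid(nx, ny, nz, px * 10.0, py * 10.0, pz * 10.0)
        save_volume_tiff(BinaryVolume3D(grid, skel.raster), path)


def load_skeleton(path, pitch_cm=None) -> Skeleton:
    path = Path(path)
    if path.suffix.lower() == ".png":
        img = load_image_png(path, None if pitch_cm is None else float(pitch_cm[0]))
        return Skeleton(img.pixels, (img.pitch_cm_per_px, img.pitch_cm_per_px))
    vol = load_binary_volume_tiff(path)
    g = vol.grid
    return Skeleton(vol.mask, pitch_cm or (g.voxel_z_mm / 10, g.voxel_y_mm / 10, g.voxel_x_mm / 10))


def skeleton_to_csv(skel: Skeleton, path) -> None:
    """Write foreground cell indices, one row per cell (x,y[,z] order)."""
    coords = np.argwhere(skel.raster)
    with open(path, "w") as fh:
        if skel.dims == 2:
            fh.write("x,y\n")
            for r, c in coords:
                fh.write(f"{c},{r}\n")
        else:
            fh.write("x,y,z\n")
            for z, r, c in coords:
                fh.write(f"{c},{r},{z}\n")
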