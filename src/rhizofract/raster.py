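"""Raster representations of root systems: 2-D binary photographs and
3-D CT-like voxel volumes, with physical pixel/voxel pitch metadata.

Geometry arrives in cm from :mod:`rhizofract.synthetic`; this module owns
all conversion to pixels/voxels.  Conventions: 0-based indices; 2-D arrays
are (row, col) = (z, x) with z increasing downward; 3-D arrays are
(slice, row, col) = (z, y, x) with slice 0 at the top.  Polyline edges are
rasterized by their *supercover* — every cell a continuous segment passes
through is marked — which guarantees that thin roots stay connected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml
from scipy import ndimage

from .synthetic import RootSystem

__all__ = [
    "BinaryImage2D",
    "VoxelGrid",
    "GrayVolume3D",
    "BinaryVolume3D",
    "paper_ct_grid",
    "pot_grid",
    "supercover",
    "rasterize_2d",
    "voxelize_3d",
    "simulate_ct",
    "grid_volume",
    "save_image_png",
    "load_image_png",
    "save_volume_tiff",
    "load_gray_volume_tiff",
    "load_binary_volume_tiff",
]


@dataclass
class BinaryImage2D:
    """Binary photograph stand-in: (row=z downward, col=x), pitch in cm/px."""

    pixels: np.ndarray
    pitch_cm_per_px: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or max(self.pixels.shape) < 2:
            raise ValueError("pixels must be a 2-D grid with a dimension >= 2")
        if self.pitch_cm_per_px <= 0:
            raise ValueError("pitch_cm_per_px must be positive")


@dataclass(frozen=True)
class VoxelGrid:
    """CT grid geometry: counts per axis and physical voxel size in mm."""

    nx: int
    ny: int
    nz: int
    voxel_x_mm: float
    voxel_y_mm: float
    voxel_z_mm: float

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be positive")
        if min(self.voxel_x_mm, self.voxel_y_mm, self.voxel_z_mm) <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple:
        """Array shape in (z, y, x) order."""
        return (self.nz, self.ny, self.nx)

    @property
    def extent_mm(self) -> tuple:
        """Physical extent (x, y, z) in mm."""
        return (self.nx * self.voxel_x_mm, self.ny * self.voxel_y_mm, self.nz * self.voxel_z_mm)


@dataclass
class GrayVolume3D:
    grid: VoxelGrid
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.grid.shape:
            raise ValueError("intensity array shape must match the grid")


@dataclass
class BinaryVolume3D:
    grid: VoxelGrid
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape must match the grid")


def paper_ct_grid() -> VoxelGrid:
    """Clinical CT geometry: 512 x 512 x 500 voxels of 0.21 x 0.21 x 0.2 mm."""
    return VoxelGrid(512, 512, 500, 0.21, 0.21, 0.2)


def pot_grid(diameter_cm: float = 15.0, height_cm: float = 13.0, n: int = 128) -> VoxelGrid:
    """Cubic-count grid covering a pot (n voxels per axis, anisotropic pitch)."""
    return VoxelGrid(n, n, n, diameter_cm * 10.0 / n, diameter_cm * 10.0 / n, height_cm * 10.0 / n)


# ---------------------------------------------------------------------------
# supercover rasterization
# ---------------------------------------------------------------------------


def supercover(p0, p1) -> np.ndarray:
    """Integer cells traversed by the continuous segment p0 -> p1.

    Coordinates are continuous cell coordinates (units of cells); a point
    with coordinate c lies in cell floor(c).  Every cell the open segment
    intersects with positive length is returned (any dimension).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    if not np.any(d):
        return np.floor(p0)[None, :].astype(np.int64)
    ts = [0.0, 1.0]
    for ax in range(len(p0)):
        if d[ax] == 0.0:
            continue
        lo, hi = sorted((p0[ax], p1[ax]))
        for k in range(math.ceil(lo), math.floor(hi) + 1):
            t = (k - p0[ax]) / d[ax]
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = np.unique(np.asarray(ts))
    mids = (ts[:-1] + ts[1:]) / 2.0
    cells = np.floor(p0[None, :] + mids[:, None] * d[None, :]).astype(np.int64)
    # include the end cells explicitly (robust at integer endpoints)
    ends = np.floor(np.vstack([p0, p1])).astype(np.int64)
    return np.unique(np.vstack([cells, ends]), axis=0)


def _mark_edges(mask: np.ndarray, cell_points: np.ndarray) -> None:
    """Supercover-mark every consecutive edge of a cell-coordinate polyline."""
    shape = np.asarray(mask.shape)
    for a, b in zip(cell_points[:-1], cell_points[1:]):
        cells = supercover(a, b)
        np.clip(cells, 0, shape - 1, out=cells)
        mask[tuple(cells.T)] = True


def rasterize_2d(system: RootSystem, pitch_cm_per_px: float, thickness_px: int = 1) -> BinaryImage2D:
    """Project a rhizobox-grown system along its thin axis onto a binary image.

    The image covers the whole rhizobox face; each polyline edge is marked by
    its 2-D supercover and the result is dilated to ``thickness_px``.
    """
    if system.domain.shape != "rhizobox":
        raise ValueError("2-D projection is defined for rhizobox-domain systems only")
    if pitch_cm_per_px <= 0:
        raise ValueError("pitch_cm_per_px must be positive")
    if thickness_px < 1:
        raise ValueError("thickness_px must be >= 1")
    width = system.domain.width_cm
    height = system.domain.height_cm
    nrows = math.ceil(height / pitch_cm_per_px) + 1
    ncols = math.ceil(width / pitch_cm_per_px) + 1
    mask = np.zeros((nrows, ncols), dtype=bool)
    for seg in system.segments:
        rows = seg.points[:, 2] / pitch_cm_per_px
        cols = (seg.points[:, 0] + width / 2.0) / pitch_cm_per_px
        _mark_edges(mask, np.column_stack([rows, cols]))
    if thickness_px > 1:
        from skimage.morphology import disk

        mask = ndimage.binary_dilation(mask, structure=disk(thickness_px // 2))
    return BinaryImage2D(mask, pitch_cm_per_px)


def voxelize_3d(system: RootSystem, grid: VoxelGrid, radius_voxels: int = 0) -> BinaryVolume3D:
    """Ground-truth binary mask of a root system on a CT voxel grid.

    The grid is centered on the sowing point in x/y with slice 0 at the
    sowing depth; a system extending beyond the grid's physical extent is an
    error naming the offending coordinate.
    """
    if radius_voxels < 0:
        raise ValueError("radius_voxels must be >= 0")
    ex, ey, ez = grid.extent_mm
    mask = np.zeros(grid.shape, dtype=bool)
    tol = 1e-6
    for seg in system.segments:
        pts_mm = seg.points * 10.0
        for x, y, z in pts_mm:
            if abs(x) > ex / 2 + tol or abs(y) > ey / 2 + tol or z < -tol or z > ez + tol:
                raise ValueError(
                    f"point ({x / 10:.3f}, {y / 10:.3f}, {z / 10:.3f}) cm "
                    "lies outside the grid's physical extent"
                )
        cz = np.clip(pts_mm[:, 2] / grid.voxel_z_mm, 0, grid.nz - tol)
        cy = np.clip((pts_mm[:, 1] + ey / 2) / grid.voxel_y_mm, 0, grid.ny - tol)
        cx = np.clip((pts_mm[:, 0] + ex / 2) / grid.voxel_x_mm, 0, grid.nx - tol)
        _mark_edges(mask, np.column_stack([cz, cy, cx]))
    if radius_voxels > 0:
        from skimage.morphology import ball

        mask = ndimage.binary_dilation(mask, structure=ball(radius_voxels))
    return BinaryVolume3D(grid, mask)


def simulate_ct(
    mask: BinaryVolume3D,
    root_intensity: float,
    medium_intensity: float,
    noise_sd: float,
    seed: int,
) -> GrayVolume3D:
    """Two-material CT surrogate: piecewise-constant intensity plus i.i.d.
    Gaussian noise (no beam hardening or partial-volume blur)."""
    if root_intensity == medium_intensity:
        raise ValueError("root and medium intensities must differ (no contrast)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    vol = np.where(mask.mask, float(root_intensity), float(medium_intensity))
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    return GrayVolume3D(mask.grid, vol)


def grid_volume(grid: VoxelGrid) -> float:
    """Physical volume of the scanned grid in dm^3."""
    mm3 = (
        grid.nx * grid.ny * grid.nz
        * grid.voxel_x_mm * grid.voxel_y_mm * grid.voxel_z_mm
    )
    return mm3 / 1.0e6


# ---------------------------------------------------------------------------
# file formats (PNG for images, multi-page TIFF for volumes, text sidecars)
# ---------------------------------------------------------------------------


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".meta.txt")


def save_image_png(image: BinaryImage2D, path) -> None:
    iio.imwrite(Path(path), (image.pixels.astype(np.uint8) * 255))
    with open(_sidecar(path), "w") as fh:
        fh.write(f"pitch_cm_per_px: {image.pitch_cm_per_px}\n")


def load_image_png(path, pitch_cm_per_px: float | None = None) -> BinaryImage2D:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # RGB(A): any nonzero channel is foreground
        arr = arr.max(axis=2)
    if pitch_cm_per_px is None:
        with open(_sidecar(path)) as fh:
            pitch_cm_per_px = float(yaml.safe_load(fh)["pitch_cm_per_px"])
    return BinaryImage2D(arr > 0, pitch_cm_per_px)


def _write_grid_sidecar(grid: VoxelGrid, path) -> None:
    with open(_sidecar(path), "w") as fh:
        for k in ("nx", "ny", "nz", "voxel_x_mm", "voxel_y_mm", "voxel_z_mm"):
            fh.write(f"{k}: {getattr(grid, k)}\n")


def _read_grid_sidecar(path) -> VoxelGrid:
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh)
    return VoxelGrid(
        int(meta["nx"]), int(meta["ny"]), int(meta["nz"]),
        float(meta["voxel_x_mm"]), float(meta["voxel_y_mm"]), float(meta["voxel_z_mm"]),
    )


def save_volume_tiff(volume, path) -> None:
    """Write a gray or binary volume as a multi-page TIFF (page = z-slice)."""
    if isinstance(volume, BinaryVolume3D):
        tifffile.imwrite(Path(path), volume.mask.astype(np.uint8) * 255)
    elif isinstance(volume, GrayVolume3D):
        tifffile.imwrite(Path(path), volume.intensities.astype(np.float32))
    else:
        raise TypeError("expected GrayVolume3D or BinaryVolume3D")
    _write_grid_sidecar(volume.grid, path)


def load_gray_volume_tiff(path, grid: VoxelGrid | None = None) -> GrayVolume3D:
    arr = tifffile.imread(Path(path))
    grid = grid or _read_grid_sidecar(path)
    return GrayVolume3D(grid, np.asarray(arr, dtype=float))


def load_binary_volume_tiff(path, grid: VoxelGrid | None = None) -> BinaryVolume3D:
    arr = tifffile.imread(Path(path))
    grid = grid or _read_grid_sidecar(path)
    return BinaryVolume3D(grid, np.asarray(arr) > 0)
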