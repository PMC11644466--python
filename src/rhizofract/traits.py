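"""Root-system traits from skeletons: total root length and fractal dimension.

Fractal dimension (FD) measures space-filling complexity.  Unlike Euclidean
dimension it is not restricted to integers (0: point, 1: straight line,
2: plane, 3: volume); a branching root skeleton typically falls between 1
and its embedding dimension.  FD is estimated by box counting in 2-D and
cube counting in 3-D: nested dyadic grids of edge ``s`` are overlaid on the
raster, the occupied cells ``N(s)`` counted, and FD taken as the ordinary
least-squares slope of ``log N(s)`` against ``log (1/s)``.

With the grid anchored at the array origin and a dyadic schedule, refining
one level multiplies counts by a factor between 1 and ``2^dims``, so every
pairwise slope — and hence the OLS slope, a convex combination of pairwise
slopes — lies in [0, dims].  FD estimates therefore cannot exceed 2.0 in
the 2-D procedure and 3.0 in the 3-D procedure, by construction.

Total root length sums the edge weights of a minimum-spanning forest over
the skeleton-cell adjacency graph (8-neighborhood in 2-D, 26 in 3-D; edge
weight = Euclidean center distance under the anisotropic pitch), which
counts every diagonal/orthogonal clique exactly once.  The total weight of
a minimum spanning forest is unique, so the trait is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

from .skeleton import Skeleton

__all__ = [
    "FDEstimate",
    "TraitRecord",
    "total_root_length",
    "count_boxes",
    "dyadic_sizes",
    "fd_boxcount",
    "fd_cubecount",
    "measure_skeleton",
]


@dataclass
class FDEstimate:
    """Box/cube-counting fit: scale schedule, counts, slope and diagnostics."""

    sizes: np.ndarray
    counts: np.ndarray
    fd: float
    intercept: float
    r_squared: float
    dims: int

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts <= 0):
            raise ValueError("occupied-box counts must be positive")
        if np.any(np.diff(self.counts) > 0):
            raise ValueError("counts must be non-increasing with box size")
        if not 0.0 <= self.fd <= self.dims:
            raise ValueError("fd must lie within [0, dims]")


@dataclass
class TraitRecord:
    """Per-plant trait row: total root length (cm) and fractal dimension."""

    plant_id: str
    archetype: str
    system: str  # "2D" or "3D"
    total_root_length_cm: float
    fd: float
    r_squared: float = float("nan")
    n_scales: int = 0

    def __post_init__(self) -> None:
        if self.system not in ("2D", "3D"):
            raise ValueError("system must be '2D' or '3D'")
        if self.total_root_length_cm < 0:
            raise ValueError("length must be >= 0")
        bound = 2.0 if self.system == "2D" else 3.0
        if not 0.0 <= self.fd <= bound:
            raise ValueError(f"fd out of [0, {bound}] for a {self.system} record")


# ---------------------------------------------------------------------------
# total root length
# ---------------------------------------------------------------------------

def _half_offsets(ndim: int):
    """Lexicographically positive neighbor offsets (4 in 2-D, 13 in 3-D)."""
    offs = []
    for off in product((-1, 0, 1), repeat=ndim):
        if off > (0,) * ndim:
            offs.append(off)
    return offs


def total_root_length(skel: Skeleton) -> float:
    """Minimum-spanning-forest length of the skeleton graph, in cm.

    Empty skeletons measure 0 with a warning rather than an error, so that
    a failed segmentation propagates as a zero-length plant.
    """
    raster = skel.raster
    if not raster.any():
        warnings.warn("empty skeleton has zero length", stacklevel=2)
        return 0.0
    ids = np.full(raster.shape, -1, dtype=np.int64)
    n = int(raster.sum())
    ids[raster] = np.arange(n)
    pitch = np.asarray(skel.pitch_cm)

    rows, cols, weights = [], [], []
    for off in _half_offsets(raster.ndim):
        src = tuple(
            slice(max(-o, 0), raster.shape[ax] - max(o, 0)) for ax, o in enumerate(off)
        )
        dst = tuple(
            slice(max(o, 0), raster.shape[ax] - max(-o, 0)) for ax, o in enumerate(off)
        )
        pair = raster[src] & raster[dst]
        if not pair.any():
            continue
        a = ids[src][pair]
        b = ids[dst][pair]
        w = float(np.linalg.norm(np.asarray(off) * pitch))
        rows.append(a)
        cols.append(b)
        weights.append(np.full(a.shape, w))
    if not rows:
        return 0.0  # isolated cells only
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return float(minimum_spanning_tree(graph).sum())


# ---------------------------------------------------------------------------
# box / cube counting
# ---------------------------------------------------------------------------

def count_boxes(skel, size: int) -> int:
    """Occupied cells of a dyadic grid of edge ``size`` anchored at the origin."""
    raster = skel.raster if isinstance(skel, Skeleton) else np.asarray(skel, dtype=bool)
    size = int(size)
    if size < 1:
        raise ValueError("box size must be >= 1")
    if size > min(raster.shape):
        raise ValueError(
            f"box size {size} exceeds the raster extent {raster.shape}"
        )
    if size == 1:
        return int(raster.sum())
    padded_shape = [-(-s // size) * size for s in raster.shape]
    padded = np.zeros(padded_shape, dtype=bool)
    padded[tuple(slice(0, s) for s in raster.shape)] = raster
    new_shape = []
    for s in padded_shape:
        new_shape.extend([s // size, size])
    blocks = padded.reshape(new_shape)
    axes = tuple(range(1, 2 * raster.ndim, 2))
    return int(blocks.any(axis=axes).sum())


def dyadic_sizes(shape) -> np.ndarray:
    """Default scale schedule: 1, 2, 4, ... up to floor(min_dim / 4)."""
    smax = min(shape) // 4
    sizes = []
    s = 1
    while s <= smax:
        sizes.append(s)
        s *= 2
    return np.asarray(sizes, dtype=int)


def _fd_fit(raster: np.ndarray, dims: int, sizes=None) -> FDEstimate:
    if not raster.any():
        raise ValueError("cannot estimate FD of an empty skeleton")
    sizes = dyadic_sizes(raster.shape) if sizes is None else np.asarray(sizes, dtype=int)
    if len(sizes) < 4:
        raise ValueError("insufficient scale range: need >= 4 box sizes")
    counts = np.array([count_boxes(raster, int(s)) for s in sizes], dtype=np.int64)
    x = -np.log(sizes.astype(float))  # log(1/size)
    y = np.log(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    fd = float(np.clip(slope, 0.0, dims))  # guard fp round-off at the bounds
    return FDEstimate(sizes, counts, fd, float(intercept), r2, dims)


def fd_boxcount(skel, sizes=None) -> FDEstimate:
    """2-D box-counting FD of a skeleton image (0 <= fd <= 2)."""
    raster = skel.raster if isinstance(skel, Skeleton) else np.asarray(skel, dtype=bool)
    if raster.ndim != 2:
        raise ValueError("fd_boxcount expects a 2-D skeleton")
    return _fd_fit(raster, 2, sizes)


def fd_cubecount(skel, sizes=None) -> FDEstimate:
    """3-D cube-counting FD of a skeleton volume (0 <= fd <= 3)."""
    raster = skel.raster if isinstance(skel, Skeleton) else np.asarray(skel, dtype=bool)
    if raster.ndim != 3:
        raise ValueError("fd_cubecount expects a 3-D skeleton")
    return _fd_fit(raster, 3, sizes)


def measure_skeleton(
    skel: Skeleton, plant_id: str, archetype: str, system: Optional[str] = None
) -> TraitRecord:
    """Convenience wrapper: both traits of one skeleton as a TraitRecord."""
    system = system or ("2D" if skel.dims == 2 else "3D")
    est = fd_boxcount(skel) if skel.dims == 2 else fd_cubecount(skel)
    return TraitRecord(
        plant_id=plant_id,
        archetype=archetype,
        system=system,
        total_root_length_cm=total_root_length(skel),
        fd=est.fd,
        r_squared=est.r_squared,
        n_scales=len(est.sizes),
    )
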