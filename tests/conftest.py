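"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from rhizofract.synthetic import Domain, RootSegment, RootSystem


@pytest.fixture
def rhizobox() -> Domain:
    return Domain.rhizobox()


@pytest.fixture
def pot() -> Domain:
    return Domain.pot()


def straight_system(p0, p1, domain: Domain, extra_segments=()) -> RootSystem:
    """A hand-built system whose taproot is the single straight edge p0->p1."""
    segs = [RootSegment(0, None, 0, np.array([p0, p1], dtype=float))]
    for i, pts in enumerate(extra_segments, start=1):
        segs.append(RootSegment(i, 0, 1, np.asarray(pts, dtype=float)))
    return RootSystem(segs, domain, 0, "line")


def brute_force_box_count(raster: np.ndarray, size: int) -> int:
    """Independent oracle: explicit loop over origin-anchored grid cells."""
    raster = np.asarray(raster, dtype=bool)
    count = 0
    starts = [range(0, s, size) for s in raster.shape]
    for origin in product(*starts):
        sl = tuple(slice(o, o + size) for o in origin)
        if raster[sl].any():
            count += 1
    return count


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def polyline_arc_length(points: np.ndarray) -> float:
    """Brute-force pairwise-distance resummation (oracle for ground truth)."""
    total = 0.0
    for p, q in zip(points[:-1], points[1:]):
        total += float(np.sqrt(((np.asarray(q) - np.asarray(p)) ** 2).sum()))
    return total
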