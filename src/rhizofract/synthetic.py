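"""Seeded stochastic generator of soybean-like root systems.

The generator grows a root system by discrete steps inside a confinement
domain (a thin rhizobox or a cylindrical pot) and records exact geometric
ground truth: every root is a polyline in cm, tagged with its branching
order (0 = taproot/primary, 1 = secondary, 2 = tertiary).

Two named archetypes bracket the qualitative contrast seen between
taproot-dominant and highly branched soybean cultivars at the V1 stage:

* ``casino_archetype`` — a highly dominant primary root, few and relatively
  short secondary roots, and almost no tertiaries;
* ``woodstock_archetype`` — many long secondary roots plus tertiaries.

Growth model
------------
The taproot starts at the sowing point (the origin; z points downward) and
advances in fixed-length steps.  At each step the heading is blended with
the downward unit vector by the ``gravitropism`` weight and then perturbed
by an isotropic Gaussian deflection.  Laterals are spawned as a Poisson
process along their parent (expected ``lateral_density_per_cm`` per cm of
parent arc length), attach at uniform positions, branch off at a Gaussian
angle from the local parent tangent with uniform azimuth, and draw their
length from a log-normal distribution specified by its natural-scale mean
and SD.  A secondary bears tertiaries with probability ``tertiary_prob``;
tertiaries use the same spawning density with shorter lengths.

Growth steps that would leave the domain are clipped at the boundary and
the next step is re-aimed inward, so every recorded point lies inside the
domain.  The length budget is consumed by realised arc length, which makes
``ground_truth_length`` of an unbranched system equal its taproot budget.

All randomness flows through one ``numpy.random.default_rng(seed)`` stream,
with draws consumed in segment-id order: equal (params, domain, seed)
reproduce the system bitwise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "Domain",
    "ArchetypeParams",
    "RootSegment",
    "RootSystem",
    "casino_archetype",
    "woodstock_archetype",
    "archetype_by_name",
    "load_archetype_params",
    "generate",
    "ground_truth_length",
    "save_system",
    "load_system",
]

_DOWN = np.array([0.0, 0.0, 1.0])

#: SD (radians, roughly) of the per-step isotropic heading deflection.
STEP_DEFLECTION_SD = 0.18

#: Laterals feel only a fraction of the taproot's gravitropic pull;
#: otherwise every lateral plunges vertically and the archetype contrast
#: in space filling disappears.
LATERAL_GRAVITROPISM_FACTOR = 0.15

#: Tertiary laterals draw lengths from the secondary-length distribution
#: scaled by this factor (tertiaries are visibly shorter than secondaries).
TERTIARY_LENGTH_SCALE = 0.35

_EPS = 1e-9


# ---------------------------------------------------------------------------
# domains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Domain:
    """Confinement domain for root growth.

    Coordinates are in cm, right-handed, z increasing downward from the
    sowing point at the top-center of the domain.

    * ``rhizobox``: ``x`` in [-width/2, width/2], ``y`` (the thin axis) in
      [-depth/2, depth/2], ``z`` in [0, height].
    * ``pot``: ``x^2 + y^2 <= (diameter/2)^2``, ``z`` in [0, height].
    """

    shape: str
    height_cm: float
    width_cm: Optional[float] = None
    depth_cm: Optional[float] = None
    diameter_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.shape not in ("rhizobox", "pot"):
            raise ValueError(f"unknown domain shape {self.shape!r}")
        if self.height_cm <= 0:
            raise ValueError("height_cm must be positive")
        if self.shape == "rhizobox":
            if self.width_cm is None or self.depth_cm is None:
                raise ValueError("rhizobox needs width_cm and depth_cm")
            if self.width_cm <= 0 or self.depth_cm <= 0:
                raise ValueError("rhizobox extents must be positive")
            if self.depth_cm >= self.width_cm:
                raise ValueError("rhizobox depth must be small vs width (quasi-planar)")
        else:
            if self.diameter_cm is None or self.diameter_cm <= 0:
                raise ValueError("pot needs positive diameter_cm")

    @classmethod
    def rhizobox(
        cls, height_cm: float = 40.6, width_cm: float = 25.4, depth_cm: float = 1.5
    ) -> "Domain":
        """Thin flat box used for 2-D photography (defaults: 40.6 x 25.4 x 1.5 cm)."""
        return cls("rhizobox", height_cm, width_cm=width_cm, depth_cm=depth_cm)

    @classmethod
    def pot(cls, diameter_cm: float = 15.0, height_cm: float = 13.0) -> "Domain":
        """Cylindrical pot used for CT scanning (defaults: 15 cm diameter, 13 cm height)."""
        return cls("pot", height_cm, diameter_cm=diameter_cm)

    # -- geometry ----------------------------------------------------------

    def contains(self, p: np.ndarray, tol: float = 1e-7) -> bool:
        x, y, z = p
        if z < -tol or z > self.height_cm + tol:
            return False
        if self.shape == "rhizobox":
            return (
                abs(x) <= self.width_cm / 2 + tol and abs(y) <= self.depth_cm / 2 + tol
            )
        r = self.diameter_cm / 2
        return x * x + y * y <= (r + tol) ** 2

    def clamp(self, p: np.ndarray) -> np.ndarray:
        """Project a point (assumed at most epsilon outside) back into the domain."""
        x, y, z = p
        z = min(max(z, 0.0), self.height_cm)
        if self.shape == "rhizobox":
            x = min(max(x, -self.width_cm / 2), self.width_cm / 2)
            y = min(max(y, -self.depth_cm / 2), self.depth_cm / 2)
        else:
            r = self.diameter_cm / 2
            rho = math.hypot(x, y)
            if rho > r:
                x *= r / rho
                y *= r / rho
        return np.array([x, y, z])

    def exit_fraction(self, p: np.ndarray, q: np.ndarray):
        """Largest t in [0, 1] with p + t(q-p) inside, and the inward normal
        of the wall limiting t (None when the full step stays inside)."""
        d = q - p
        t_best, normal = 1.0, None

        def consider(t, n):
            nonlocal t_best, normal
            if t < t_best - 1e-15:
                t_best, normal = t, n

        # z slabs
        if d[2] > _EPS:
            consider((self.height_cm - p[2]) / d[2], np.array([0.0, 0.0, -1.0]))
        elif d[2] < -_EPS:
            consider((0.0 - p[2]) / d[2], np.array([0.0, 0.0, 1.0]))
        if self.shape == "rhizobox":
            for ax, half in ((0, self.width_cm / 2), (1, self.depth_cm / 2)):
                if d[ax] > _EPS:
                    n = np.zeros(3)
                    n[ax] = -1.0
                    consider((half - p[ax]) / d[ax], n)
                elif d[ax] < -_EPS:
                    n = np.zeros(3)
                    n[ax] = 1.0
                    consider((-half - p[ax]) / d[ax], n)
        else:
            # |p_xy + t d_xy|^2 = r^2, take the first positive root
            r = self.diameter_cm / 2
            a = d[0] * d[0] + d[1] * d[1]
            if a > _EPS * _EPS:
                b = 2 * (p[0] * d[0] + p[1] * d[1])
                c = p[0] * p[0] + p[1] * p[1] - r * r
                disc = b * b - 4 * a * c
                if disc >= 0:
                    t_hit = (-b + math.sqrt(disc)) / (2 * a)
                    if t_hit >= 0:
                        hit = p + t_hit * d
                        rho = math.hypot(hit[0], hit[1])
                        n = np.array([-hit[0], -hit[1], 0.0]) / max(rho, _EPS)
                        consider(t_hit, n)
        t_best = min(max(t_best, 0.0), 1.0)
        return t_best, normal


# ---------------------------------------------------------------------------
# archetypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchetypeParams:
    """Parameters of the stochastic growth model (lengths in cm, angles in deg)."""

    taproot_length_cm: float
    step_cm: float
    lateral_density_per_cm: float
    lateral_length_mean_cm: float
    lateral_length_sd_cm: float
    tertiary_prob: float
    branch_angle_mean_deg: float
    branch_angle_sd_deg: float
    gravitropism: float

    def __post_init__(self) -> None:
        if self.taproot_length_cm <= 0:
            raise ValueError("taproot_length_cm must be positive")
        if self.step_cm <= 0:
            raise ValueError("step_cm must be positive")
        for name in ("lateral_density_per_cm", "lateral_length_mean_cm", "lateral_length_sd_cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.tertiary_prob <= 1.0:
            raise ValueError("tertiary_prob must lie in [0, 1]")
        if not 0.0 <= self.gravitropism <= 1.0:
            raise ValueError("gravitropism must lie in [0, 1]")


def casino_archetype() -> ArchetypeParams:
    """Taproot-dominant archetype: few, short secondaries, almost no tertiaries."""
    return ArchetypeParams(
        taproot_length_cm=20.0,
        step_cm=0.5,
        lateral_density_per_cm=0.25,
        lateral_length_mean_cm=1.0,
        lateral_length_sd_cm=0.5,
        tertiary_prob=0.02,
        branch_angle_mean_deg=70.0,
        branch_angle_sd_deg=15.0,
        gravitropism=0.85,
    )


def woodstock_archetype() -> ArchetypeParams:
    """Highly branched archetype: many long secondaries and frequent tertiaries."""
    return ArchetypeParams(
        taproot_length_cm=24.0,
        step_cm=0.5,
        lateral_density_per_cm=2.0,
        lateral_length_mean_cm=4.0,
        lateral_length_sd_cm=2.0,
        tertiary_prob=0.6,
        branch_angle_mean_deg=65.0,
        branch_angle_sd_deg=20.0,
        gravitropism=0.75,
    )


_ARCHETYPES = {"casino": casino_archetype, "woodstock": woodstock_archetype}


def archetype_by_name(name: str) -> ArchetypeParams:
    try:
        return _ARCHETYPES[name.lower()]()
    except KeyError:
        raise ValueError(
            f"unknown archetype {name!r}; choose from {sorted(_ARCHETYPES)}"
        ) from None


def load_archetype_params(path, base: Optional[str] = None) -> ArchetypeParams:
    """Read archetype parameters from a plain-text key-value (YAML) file.

    Keys match :class:`ArchetypeParams` fields; missing keys fall back to the
    ``base`` archetype (default: casino).
    """
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    if not isinstance(overrides, dict):
        raise ValueError("archetype config must be a key-value mapping")
    params = archetype_by_name(base or overrides.pop("base", "casino"))
    field_names = {f.name for f in dataclasses.fields(ArchetypeParams)}
    unknown = set(overrides) - field_names
    if unknown:
        raise ValueError(f"unknown archetype parameter(s): {sorted(unknown)}")
    return dataclasses.replace(params, **{k: float(v) for k, v in overrides.items()})


# ---------------------------------------------------------------------------
# root system containers
# ---------------------------------------------------------------------------


@dataclass
class RootSegment:
    """One root as an ordered polyline of 3-D points (cm)."""

    id: int
    parent_id: Optional[int]
    order: int
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("a root segment needs >= 2 three-dimensional points")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps <= 0):
            raise ValueError("consecutive polyline points must be distinct")
        if self.order < 0:
            raise ValueError("order must be >= 0")

    @property
    def arc_length_cm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def point_at(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        """Point and unit tangent at arc-length position ``s`` along the polyline."""
        deltas = np.diff(self.points, axis=0)
        lens = np.linalg.norm(deltas, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        s = min(max(s, 0.0), cum[-1])
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(lens) - 1)
        frac = (s - cum[i]) / lens[i]
        return self.points[i] + frac * deltas[i], deltas[i] / lens[i]


@dataclass
class RootSystem:
    """A full root system plus its provenance (domain, seed, archetype)."""

    segments: list
    domain: Domain
    seed: int
    archetype_name: str

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a root system must contain at least one segment")
        by_id = {s.id: s for s in self.segments}
        if len(by_id) != len(self.segments):
            raise ValueError("segment ids must be unique")
        primaries = [s for s in self.segments if s.order == 0]
        if len(primaries) != 1:
            raise ValueError("exactly one order-0 (taproot) segment required")
        for s in self.segments:
            if s.order == 0:
                if s.parent_id is not None:
                    raise ValueError("the taproot has no parent")
                continue
            parent = by_id.get(s.parent_id)
            if parent is None or parent.order != s.order - 1:
                raise ValueError(
                    f"segment {s.id}: parent must exist with order {s.order - 1}"
                )
            if s.parent_id >= s.id:
                raise ValueError("parent ids must precede child ids (acyclic)")
        for s in self.segments:
            for p in s.points:
                if not self.domain.contains(p):
                    raise ValueError(f"point {tuple(p)} outside the domain")


def ground_truth_length(system: RootSystem) -> float:
    """Exact total root length (cm): sum of polyline arc lengths."""
    return float(sum(seg.arc_length_cm for seg in system.segments))


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > _EPS else _DOWN.copy()


def _grow_polyline(rng, start, direction, length_cm, step_cm, gravitropism, domain):
    """Grow one root polyline; budget is consumed by realised arc length."""
    p = domain.clamp(np.asarray(start, dtype=float))
    d = _unit(np.asarray(direction, dtype=float))
    pts = [p]
    remaining = float(length_cm)
    max_iter = int(length_cm / step_cm) * 4 + 64
    for _ in range(max_iter):
        if remaining <= 1e-9:
            break
        d = _unit((1.0 - gravitropism) * d + gravitropism * _DOWN)
        d = _unit(d + rng.normal(0.0, STEP_DEFLECTION_SD, size=3))
        step = min(step_cm, remaining)
        q = p + step * d
        t, normal = domain.exit_fraction(p, q)
        if t <= 1e-6:
            # flush against a wall: re-aim inward and retry (costs an iteration)
            d = _unit(d + 2.0 * normal) if normal is not None else _DOWN.copy()
            continue
        q = domain.clamp(p + t * (q - p))
        seg_len = float(np.linalg.norm(q - p))
        if seg_len <= 1e-12:
            continue
        pts.append(q)
        remaining -= seg_len
        p = q
        if normal is not None and t < 1.0:
            d = _unit(d + 1.5 * normal)
    if len(pts) < 2:
        return None
    return np.array(pts)


def _branch_direction(rng, tangent, angle_mean_deg, angle_sd_deg):
    """Unit vector at a Gaussian polar angle from ``tangent``, uniform azimuth."""
    theta = math.radians(rng.normal(angle_mean_deg, angle_sd_deg))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    t = _unit(tangent)
    # orthonormal frame around the tangent
    helper = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(t, helper))
    v = np.cross(t, u)
    return _unit(
        math.cos(theta) * t + math.sin(theta) * (math.cos(phi) * u + math.sin(phi) * v)
    )


def _lognormal_params(mean: float, sd: float):
    """Convert a natural-scale mean/SD to log-space (mu, sigma)."""
    if mean <= 0:
        return None
    if sd <= 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate(params: ArchetypeParams, domain: Domain, seed: int,
             archetype_name: str = "custom") -> RootSystem:
    """Grow one root system; deterministic for fixed (params, domain, seed)."""
    if params.step_cm <= 0:
        raise ValueError("step_cm must be positive")
    rng = np.random.default_rng(seed)
    segments: list[RootSegment] = []

    tap_pts = _grow_polyline(
        rng,
        start=np.zeros(3),
        direction=_DOWN,
        length_cm=params.taproot_length_cm,
        step_cm=params.step_cm,
        gravitropism=params.gravitropism,
        domain=domain,
    )
    if tap_pts is None:
        raise RuntimeError("taproot growth degenerated (domain too tight)")
    segments.append(RootSegment(0, None, 0, tap_pts))

    lateral_grav = params.gravitropism * LATERAL_GRAVITROPISM_FACTOR
    i = 0
    while i < len(segments):
        parent = segments[i]
        i += 1
        if parent.order >= 2:
            continue  # tertiaries do not branch further
        if parent.order == 1 and rng.random() >= params.tertiary_prob:
            continue
        scale = TERTIARY_LENGTH_SCALE if parent.order == 1 else 1.0
        ln = _lognormal_params(
            params.lateral_length_mean_cm * scale, params.lateral_length_sd_cm * scale
        )
        arc = parent.arc_length_cm
        n_lat = rng.poisson(params.lateral_density_per_cm * arc)
        if ln is None or n_lat == 0:
            continue
        positions = np.sort(rng.uniform(0.0, arc, size=n_lat))
        for s in positions:
            attach, tangent = parent.point_at(float(s))
            direction = _branch_direction(
                rng, tangent, params.branch_angle_mean_deg, params.branch_angle_sd_deg
            )
            mu, sigma = ln
            length = float(rng.lognormal(mu, sigma))
            if length < params.step_cm * 0.2:
                continue  # too short to render
            pts = _grow_polyline(
                rng, attach, direction, length, params.step_cm, lateral_grav, domain
            )
            if pts is None:
                continue
            segments.append(
                RootSegment(len(segments), parent.id, parent.order + 1, pts)
            )
    return RootSystem(segments, domain, int(seed), archetype_name)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _meta_path(path) -> Path:
    return Path(path).with_suffix(".meta.txt")


def save_system(system: RootSystem, path) -> None:
    """Write one row per polyline point plus a plain-text metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("segment_id,parent_id,order,x_cm,y_cm,z_cm\n")
        for seg in system.segments:
            parent = "" if seg.parent_id is None else str(seg.parent_id)
            for x, y, z in seg.points:
                fh.write(f"{seg.id},{parent},{seg.order},{x:.9g},{y:.9g},{z:.9g}\n")
    meta = {
        "seed": system.seed,
        "archetype": system.archetype_name,
        "domain_shape": system.domain.shape,
        "height_cm": system.domain.height_cm,
    }
    if system.domain.shape == "rhizobox":
        meta["width_cm"] = system.domain.width_cm
        meta["depth_cm"] = system.domain.depth_cm
    else:
        meta["diameter_cm"] = system.domain.diameter_cm
    with open(_meta_path(path), "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}: {v}\n")


def load_system(path) -> RootSystem:
    path = Path(path)
    with open(_meta_path(path)) as fh:
        meta = yaml.safe_load(fh)
    if meta["domain_shape"] == "rhizobox":
        domain = Domain.rhizobox(meta["height_cm"], meta["width_cm"], meta["depth_cm"])
    else:
        domain = Domain.pot(meta["diameter_cm"], meta["height_cm"])
    rows: dict[int, dict] = {}
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        assert header[0] == "segment_id"
        for line in fh:
            sid, parent, order, x, y, z = line.rstrip("\n").split(",")
            rec = rows.setdefault(
                int(sid),
                {"parent": None if parent == "" else int(parent), "order": int(order), "pts": []},
            )
            rec["pts"].append((float(x), float(y), float(z)))
    segments = [
        RootSegment(sid, rec["parent"], rec["order"], np.array(rec["pts"]))
        for sid, rec in sorted(rows.items())
    ]
    return RootSystem(segments, domain, int(meta["seed"]), str(meta["archetype"]))
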