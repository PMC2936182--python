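"""Geometric model of the GammaMed Plus HDR source.

The source is exactly cylindrically symmetric, so every region is an
(r, z) box in cylindrical coordinates: an Ir70/Pt30 active core, an air (or
vacuum) gap on the lateral and distal sides, an AISI 316L capsule, a tapered
distal tip approximated by three stacked cylindrical slices, and a proximal
drive cable of compacted-steel density.

Axis convention: the long axis is z, the polar angle theta = 0 deg points
from the core center through the distal tip, and the cable occupies angles
near 180 deg.  All lengths in cm.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SourceGeometry",
    "Region",
    "classify_point",
    "sample_emission_point",
    "trace_segments",
]

MEDIUM = "medium"


@dataclass(frozen=True)
class Region:
    name: str
    material: str
    r_max: float
    z_min: float
    z_max: float
    r_min: float = 0.0

    def contains(self, s: float, z: float) -> bool:
        return (self.r_min <= s < self.r_max) and (self.z_min <= z < self.z_max)


@dataclass(frozen=True)
class SourceGeometry:
    """Nested-cylinder model; defaults reproduce the modeled source.

    Core: radius 0.03 cm, half-length 0.175 cm.  Capsule: inner radius
    0.035 cm, outer 0.045 cm.  Tip: slices of thickness 0.006, 0.005,
    0.005 cm with radii 0.035, 0.030, 0.012 cm stacked distally.  Cable:
    radius 0.045 cm, default length 6 cm, density 5.6 g/cm^3.
    """

    core_radius: float = 0.03
    core_half_length: float = 0.175
    capsule_inner_radius: float = 0.035
    capsule_outer_radius: float = 0.045
    axial_gap: float = 0.005
    tip_slices: tuple = ((0.006, 0.035), (0.005, 0.030), (0.005, 0.012))
    cable_length: float = 6.0
    gap_material: str = "gap_air"
    medium: str = "water"
    regions: tuple = field(init=False)

    def __post_init__(self):
        if not (0 < self.core_radius < self.capsule_inner_radius
                < self.capsule_outer_radius):
            raise ValueError("radii must satisfy core < capsule inner < outer")
        zc = self.core_half_length
        z_gap_top = zc + self.axial_gap
        regs = [
            Region("core", "core_alloy", self.core_radius, -zc, zc),
            Region("lateral_gap", self.gap_material, self.capsule_inner_radius,
                   -zc, zc, r_min=self.core_radius),
            Region("axial_gap", self.gap_material, self.capsule_inner_radius,
                   zc, z_gap_top),
        ]
        z = z_gap_top
        # capsule side wall spans core + gap, up to the base of the tip
        regs.append(Region("capsule_wall", "capsule_steel",
                           self.capsule_outer_radius, -zc, z,
                           r_min=self.capsule_inner_radius))
        for i, (t, rad) in enumerate(self.tip_slices):
            regs.append(Region(f"tip_{i}", "capsule_steel", rad, z, z + t))
            z += t
        regs.append(Region("cable", "cable_steel", self.capsule_outer_radius,
                           -zc - self.cable_length, -zc))
        object.__setattr__(self, "regions", tuple(regs))

    @property
    def active_length(self) -> float:
        """Active length L used by the TG-43 line-source geometry factor."""
        return 2 * self.core_half_length

    @property
    def bounding_radius(self) -> float:
        return self.capsule_outer_radius

    @property
    def bounding_z(self) -> tuple:
        return (self.regions[-1].z_min, self.regions[-2].z_max)

    def surfaces(self):
        """Unique cylinder radii and z planes bounding any region."""
        radii = sorted({r.r_max for r in self.regions}
                       | {r.r_min for r in self.regions if r.r_min > 0})
        zs = sorted({r.z_min for r in self.regions}
                    | {r.z_max for r in self.regions})
        return np.array(radii), np.array(zs)


def classify_point(geometry: SourceGeometry, position) -> tuple:
    """Region name and material at a 3-D point (cm).

    Every finite point classifies; outside all source regions the result is
    ``("medium", geometry.medium)``.
    """
    x, y, z = (float(c) for c in position)
    if not all(np.isfinite((x, y, z))):
        raise ValueError("coordinates must be finite")
    s = np.hypot(x, y)
    for reg in geometry.regions:
        if reg.contains(s, z):
            return reg.name, reg.material
    return MEDIUM, geometry.medium


def sample_emission_point(
    geometry: SourceGeometry, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Uniform points in the active-core cylinder, shape (size, 3)."""
    s = geometry.core_radius * np.sqrt(rng.random(size))
    phi = 2 * np.pi * rng.random(size)
    z = geometry.core_half_length * (2 * rng.random(size) - 1)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _step_to_boundary(geometry, p, u, radii, zplanes):
    """Distance to the nearest region surface crossing along direction u."""
    x, y, z = p
    ux, uy, uz = u
    best = np.inf
    a = ux * ux + uy * uy
    b = x * ux + y * uy
    c0 = x * x + y * y
    if a > 0:
        for R in radii:
            disc = b * b - a * (c0 - R * R)
            if disc > 0:
                sq = np.sqrt(disc)
                for t in ((-b - sq) / a, (-b + sq) / a):
                    if 1e-12 < t < best:
                        best = t
    if uz != 0:
        for zp in zplanes:
            t = (zp - z) / uz
            if 1e-12 < t < best:
                best = t
    return best


def trace_segments(geometry: SourceGeometry, origin, direction):
    """Ordered (material, path length) segments from ``origin`` along
    ``direction`` until the ray exits into the surrounding medium.

    The direction must be a unit vector (|u| = 1 within 1e-9).  A ray whose
    origin is already in the medium and never enters the source returns an
    empty list.
    """
    u = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    p = np.asarray(origin, dtype=float).copy()
    radii, zplanes = geometry.surfaces()
    rb = geometry.bounding_radius
    z_lo, z_hi = geometry.bounding_z

    segments = []
    guard = 0
    while guard < 10_000:
        guard += 1
        name, material = classify_point(geometry, p)
        if name == MEDIUM:
            s = np.hypot(p[0], p[1])
            if s < rb and z_lo <= p[2] <= z_hi:
                # medium pocket beside the tapered tip: step through it
                t = _step_to_boundary(geometry, p, u, radii, zplanes)
                if not np.isfinite(t):
                    break
                p = p + (t + 1e-9) * u
                continue
            # possibly re-enter the source bounding box; find entry distance
            t_in = _entry_distance(p, u, rb, z_lo, z_hi)
            if not np.isfinite(t_in):
                break
            p = p + (t_in + 1e-9) * u
            continue
        t = _step_to_boundary(geometry, p, u, radii, zplanes)
        if not np.isfinite(t):
            break
        if segments and segments[-1][0] == material:
            segments[-1] = (material, segments[-1][1] + t)
        else:
            segments.append((material, t))
        p = p + (t + 1e-9) * u
    return segments


def _entry_distance(p, u, rb, z_lo, z_hi):
    """Entry distance of a ray into the source bounding cylinder, or inf."""
    x, y, z = p
    ux, uy, uz = u
    a = ux * ux + uy * uy
    t_lo, t_hi = 0.0, np.inf
    if a > 0:
        b = x * ux + y * uy
        disc = b * b - a * (x * x + y * y - rb * rb)
        if disc <= 0:
            return np.inf
        sq = np.sqrt(disc)
        t_lo = max(t_lo, (-b - sq) / a)
        t_hi = min(t_hi, (-b + sq) / a)
    elif x * x + y * y >= rb * rb:
        return np.inf
    if uz != 0:
        t1, t2 = (z_lo - z) / uz, (z_hi - z) / uz
        t_lo = max(t_lo, min(t1, t2))
        t_hi = min(t_hi, max(t1, t2))
    elif not (z_lo <= z <= z_hi):
        return np.inf
    if t_hi <= t_lo or t_hi <= 1e-12:
        return np.inf
    return max(t_lo, 1e-12)
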