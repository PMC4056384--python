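"""Collimator lines of response, geometric efficiency, and sizing.

Coordinate convention: the detector (crystal) plane is z = 0 with the
object space at z > 0.  For a pinhole collimator the aperture sits at
(0, 0, F) and every line of response (LOR) passes through it; for a
parallel-hole collimator LORs run along +z.  The LOR parameter l is the
distance along the ray measured from the crystal plane (parallel) or
from the aperture (pinhole); in both cases the parameterization has unit
speed, i.e. l is Euclidean arclength (the sqrt(F^2+x^2+y^2) factors in
the pinhole form cancel in |d(point)/dl|).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "Collimator",
    "LineOfResponse",
    "parallel_lor",
    "pinhole_lor",
    "geometric_efficiency",
    "lead_wall_mass",
]

# hexagonal hole-packing constant in the standard parallel-hole
# sensitivity formula g = (K d^2 / (l (d + t)))^2
HEX_PACKING_K = 0.26


@dataclass(frozen=True)
class Collimator:
    """Parallel-hole or pinhole collimator description (cm)."""

    kind: Literal["parallel", "pinhole"]
    focal_length: float | None = None       # pinhole: crystal-aperture distance F
    aperture_diameter: float | None = None  # pinhole
    hole_diameter: float | None = None      # parallel
    hole_length: float | None = None        # parallel
    septal_thickness: float | None = None   # parallel
    front_wall: tuple[float, float, float] | None = None  # width, height, thickness

    def __post_init__(self) -> None:
        if self.kind == "pinhole":
            if self.focal_length is None or self.focal_length <= 0:
                raise ValueError("pinhole collimator requires focal_length > 0")
            if self.aperture_diameter is not None and self.aperture_diameter <= 0:
                raise ValueError("aperture_diameter must be positive")
        elif self.kind == "parallel":
            for name in ("hole_diameter", "hole_length", "septal_thickness"):
                v = getattr(self, name)
                if v is not None and v <= 0:
                    raise ValueError(f"{name} must be positive")
        else:
            raise ValueError(f"unknown collimator kind {self.kind!r}")


@dataclass(frozen=True)
class LineOfResponse:
    """Parametric ray (x'(l), y'(l), z'(l)) for a detector pixel.

    Parallel:  x'(l) = x,  y'(l) = y,  z'(l) = l.
    Pinhole:   x'(l) = -l x / s,  y'(l) = -l y / s,  z'(l) = F + l F / s,
               with s = sqrt(F^2 + x^2 + y^2)  (pinhole image inversion).
    """

    pixel: tuple[float, float]
    kind: Literal["parallel", "pinhole"]
    focal_length: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "pinhole" and (self.focal_length is None
                                       or self.focal_length <= 0):
            raise ValueError("pinhole LOR requires focal_length > 0")

    @property
    def origin(self) -> np.ndarray:
        """point_at(0): crystal plane (parallel) or aperture (pinhole)."""
        if self.kind == "parallel":
            return np.array([self.pixel[0], self.pixel[1], 0.0])
        return np.array([0.0, 0.0, self.focal_length])

    @property
    def direction(self) -> np.ndarray:
        """Unit direction d(point)/dl (constant: the ray is affine in l)."""
        if self.kind == "parallel":
            return np.array([0.0, 0.0, 1.0])
        x, y = self.pixel
        s = np.sqrt(self.focal_length**2 + x**2 + y**2)
        return np.array([-x / s, -y / s, self.focal_length / s])

    def point_at(self, l):
        """Position(s) on the ray at parameter l (arclength, cm)."""
        l = np.asarray(l, dtype=float)
        pt = self.origin + np.multiply.outer(l, self.direction)
        return pt


def parallel_lor(x: float, y: float) -> LineOfResponse:
    """LOR of the pixel (x, y) behind a parallel-hole collimator."""
    return LineOfResponse(pixel=(float(x), float(y)), kind="parallel")


def pinhole_lor(x: float, y: float, focal_length: float) -> LineOfResponse:
    """LOR of the pixel (x, y) through a pinhole aperture at (0, 0, F)."""
    if focal_length <= 0:
        raise ValueError("focal length must be positive")
    return LineOfResponse(pixel=(float(x), float(y)), kind="pinhole",
                          focal_length=float(focal_length))


def geometric_efficiency(collimator: Collimator, point) -> float:
    """Geometric detection efficiency G at a source point (x', y', z').

    Parallel hole: the standard distance-independent sensitivity
    (K d^2 / (l (d+t)))^2 with K = 0.26 (hexagonal packing).  Pinhole:
    d_eff^2 sin^3(theta) / (16 h^2) with h the source-aperture distance
    and theta the incidence angle on the aperture plane.  Purely
    geometric -- intrinsic crystal efficiency is applied separately by
    the camera model.
    """
    point = np.asarray(point, dtype=float)
    z = point[..., 2]
    if collimator.kind == "parallel":
        if np.any(z <= 0):
            raise ValueError("source point must be in front of the collimator")
        d = collimator.hole_diameter or 0.34
        t = collimator.septal_thickness or 0.14
        length = collimator.hole_length or 4.2
        g = (HEX_PACKING_K * d**2 / (length * (d + t))) ** 2
        return g * np.ones_like(z) if z.ndim else float(g)
    # pinhole
    f = collimator.focal_length
    if np.any(z <= f):
        raise ValueError("source point must be beyond the pinhole aperture")
    d_eff = collimator.aperture_diameter or 0.8
    aperture = np.array([0.0, 0.0, f])
    delta = point - aperture
    h = np.sqrt((delta**2).sum(axis=-1))
    sin_theta = (z - f) / h
    g = d_eff**2 * sin_theta**3 / (16.0 * h**2)
    return g if g.ndim else float(g)


def lead_wall_mass(width: float, height: float, thickness: float,
                   density: float = 11.34) -> float:
    """Mass (kg) of the collimator front wall: w * h * t * rho / 1000.

    The default density is bulk lead; a 45 x 25 cm wall at 5 cm thickness
    comes to ~64 kg, the practical gantry-load limit for a single-slab
    pinhole housing.
    """
    for name, v in [("width", width), ("height", height),
                    ("thickness", thickness), ("density", density)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return width * height * thickness * density / 1000.0
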