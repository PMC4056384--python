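"""Phantom generators and Poisson acquisition simulation.

Everything the other modules need for testing and demonstration is
generated here programmatically: the point-source-under-water validation
object (a hot voxel with a perpex shell, the bench object used to
validate bremsstrahlung camera models), a primitive-based liver phantom
(ellipsoid with hot/cold spheres), and seed-reproducible Poisson
acquisitions through the forward projector and detector response.

Default camera: 45 x 25 cm detector at 5 mm pixels, pinhole with 8 mm
aperture and 15 cm focal length; an ideal energy response (r = 0, unit
intrinsic efficiency) over the extended (50, 350) keV window, matching
the idealized model under which energy encodes depth exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

from .forward import (CameraModel, EnergySpectrum, Phantom,
                      apply_detector_response, project)
from .geometry import Collimator
from .physics import MaterialLibrary, default_library

__all__ = [
    "Primitive",
    "PhantomSpec",
    "AcquisitionSpec",
    "default_camera",
    "point_source_phantom",
    "liver_phantom",
    "generate_acquisition",
    "reference_peak_spectrum",
]


def default_camera(kind: Literal["pinhole", "parallel"] = "pinhole",
                   **overrides) -> CameraModel:
    """The package's default camera geometry (see module docstring)."""
    if kind == "pinhole":
        coll = Collimator(kind="pinhole", focal_length=15.0,
                          aperture_diameter=0.8,
                          front_wall=(45.0, 25.0, 5.0))
    else:
        coll = Collimator(kind="parallel", hole_diameter=0.40,
                          hole_length=4.0, septal_thickness=0.32)
    defaults = dict(collimator=coll, crystal=None, resolution_r=0.0,
                    window=(50.0, 350.0), pixel_pitch=0.5,
                    extent=(45.0, 25.0))
    defaults.update(overrides)
    return CameraModel(**defaults)


# ---------------------------------------------------------------------------
# phantoms


@dataclass(frozen=True)
class Primitive:
    """Sphere / ellipsoid / box with uniform activity concentration."""

    kind: Literal["sphere", "ellipsoid", "box"]
    center: tuple[float, float, float]      # cm
    size: tuple[float, float, float]        # radii, or box half-widths
    activity_concentration: float = 0.0     # Bq / cm^3
    medium: str = "water"

    def __post_init__(self) -> None:
        if self.activity_concentration < 0:
            raise ValueError("activity concentration must be nonnegative")
        if any(s <= 0 for s in self.size):
            raise ValueError("primitive size must be positive")

    def contains(self, x, y, z) -> np.ndarray:
        cx, cy, cz = self.center
        sx, sy, sz = self.size
        if self.kind == "box":
            return (np.abs(x - cx) <= sx) & (np.abs(y - cy) <= sy) \
                & (np.abs(z - cz) <= sz)
        return ((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2 \
            + ((z - cz) / sz) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Grid description plus a primitive list (later primitives win)."""

    grid_shape: tuple[int, int, int]
    voxel_size: float | tuple[float, float, float]
    primitives: tuple[Primitive, ...] = ()
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_medium: str = "air"

    def voxel(self) -> tuple[float, float, float]:
        v = self.voxel_size
        return (v, v, v) if np.isscalar(v) else tuple(v)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        prims = tuple(Primitive(**{**p, "center": tuple(p["center"]),
                                   "size": tuple(p["size"])})
                      for p in d.pop("primitives", []))
        return cls(grid_shape=tuple(d["grid_shape"]),
                   voxel_size=d["voxel_size"] if np.isscalar(d["voxel_size"])
                   else tuple(d["voxel_size"]),
                   primitives=prims,
                   origin=tuple(d.get("origin", (0.0, 0.0, 0.0))),
                   background_medium=d.get("background_medium", "air"))


def liver_phantom(spec: PhantomSpec, subsample: int = 2,
                  library: MaterialLibrary | None = None) -> Phantom:
    """Voxelize a primitive list onto the grid (deterministic).

    Activity is anti-aliased by `subsample`^3 sub-voxel sampling so the
    total activity of a primitive converges to concentration x analytic
    volume as the voxels refine; the medium label uses center inclusion,
    overlaps resolved last-wins.  Primitives must intersect the grid.
    """
    lib = library or default_library()
    nx, ny, nz = spec.grid_shape
    vx, vy, vz = spec.voxel()
    lo = np.asarray(spec.origin, dtype=float)
    hi = lo + np.array([nx * vx, ny * vy, nz * vz])

    medium_names = [spec.background_medium]
    for p in spec.primitives:
        name = lib.canonical_name(p.medium)
        if name not in medium_names:
            medium_names.append(name)

    xc = lo[0] + (np.arange(nx) + 0.5) * vx
    yc = lo[1] + (np.arange(ny) + 0.5) * vy
    zc = lo[2] + (np.arange(nz) + 0.5) * vz
    gx, gy, gz = np.meshgrid(xc, yc, zc, indexing="ij")

    # sub-voxel offsets for activity anti-aliasing
    s = max(1, int(subsample))
    offs = (np.arange(s) + 0.5) / s - 0.5
    ox, oy, oz = np.meshgrid(offs * vx, offs * vy, offs * vz, indexing="ij")
    sub = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])

    activity = np.zeros(spec.grid_shape)
    medium = np.zeros(spec.grid_shape, dtype=np.int16)
    voxel_volume = vx * vy * vz
    for p in spec.primitives:
        c = np.asarray(p.center)
        r = np.asarray(p.size)
        if np.any(c - r < lo) or np.any(c + r > hi):
            raise ValueError(f"primitive {p.kind} at {p.center} extends "
                             "outside the grid")
        frac = np.zeros(spec.grid_shape)
        for dx, dy, dz in sub:
            frac += p.contains(gx + dx, gy + dy, gz + dz)
        frac /= len(sub)
        inside = frac > 0
        # last-wins: a later primitive replaces activity where it covers
        activity[inside] = (p.activity_concentration * voxel_volume
                            * frac[inside])
        code = medium_names.index(lib.canonical_name(p.medium))
        medium[p.contains(gx, gy, gz)] = code

    return Phantom(activity=activity, medium=medium,
                   medium_names=tuple(medium_names),
                   voxel_size=(vx, vy, vz), origin=tuple(lo))


def point_source_phantom(depth: float, shell_thickness: float = 1.0,
                         source_distance: float = 20.0,
                         activity: float = 1.0,
                         voxel_size: float = 0.5,
                         transverse_extent: float = 10.0,
                         margin_behind: float = 2.0) -> Phantom:
    """A hot voxel under `depth` cm of water, with a perpex shell.

    The source sits on the camera axis at the fixed detector distance
    `source_distance`; water covers it from the detector side so the
    surface faces the collimator at l = source_distance - depth.  A
    perpex cube of half-width `shell_thickness` surrounds the source
    voxel (the bench validation object); everything else in the slab is
    water, outside it air.  Deterministic; the voxelized total activity
    equals `activity` exactly.
    """
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    if depth > source_distance:
        raise ValueError("depth cannot exceed the source distance")
    v = float(voxel_size)
    nt = int(round(transverse_extent / v))
    nt += (nt + 1) % 2  # odd so one voxel straddles the axis
    z_hi = source_distance + max(margin_behind, shell_thickness + v)
    # z origin at -v/2 puts voxel centers on multiples of v, so the
    # source center lands exactly at source_distance when it divides v
    nz = int(np.ceil((z_hi + v / 2) / v))
    shape = (nt, nt, nz)
    half = nt * v / 2
    origin = (-half, -half, -v / 2)

    zc = np.arange(nz) * v  # voxel centers
    k_src = int(np.argmin(np.abs(zc - source_distance)))
    i_src = nt // 2
    src_z = float(zc[k_src])

    medium_names = ("air", "water", "perpex")
    medium = np.zeros(shape, dtype=np.int16)
    # snap the surface to the nearest voxel boundary ((k - 1/2) v)
    surface_z = (np.round((src_z - depth) / v - 0.5) + 0.5) * v
    surface_z = max(surface_z, -v / 2)
    in_water = zc > surface_z
    medium[:, :, in_water] = 1
    if shell_thickness > 0:
        xs = (np.arange(nt) + 0.5) * v - half
        gx, gy, gz = np.meshgrid(xs, xs, zc, indexing="ij")
        shell = (np.abs(gx) <= shell_thickness) \
            & (np.abs(gy) <= shell_thickness) \
            & (np.abs(gz - src_z) <= shell_thickness)
        medium[shell & (medium > 0)] = 2

    act = np.zeros(shape)
    act[i_src, i_src, k_src] = activity
    if depth > 0 and medium[i_src, i_src, k_src] == 0:
        raise ValueError("source voxel fell outside the phantom medium")
    meta = {"source_center_z": src_z, "surface_z": float(surface_z),
            "geometric_depth": src_z - float(surface_z)}
    return Phantom(activity=act, medium=medium, medium_names=medium_names,
                   voxel_size=(v, v, v), origin=origin, meta=meta)


# ---------------------------------------------------------------------------
# acquisition


@dataclass(frozen=True)
class AcquisitionSpec:
    """Everything needed for a reproducible synthetic acquisition."""

    phantom: Phantom
    camera: CameraModel
    live_time: float                 # s
    seed: int
    energy_edges: np.ndarray | None = None
    pixels: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.live_time < 0:
            raise ValueError("live time must be nonnegative")

    def provenance(self) -> dict:
        cam = self.camera
        blob = json.dumps({
            "collimator": asdict(cam.collimator),
            "window": cam.window, "r": cam.resolution_r,
            "pitch": cam.pixel_pitch, "extent": cam.extent,
            "live_time": self.live_time,
            "phantom_shape": self.phantom.shape,
            "voxel": self.phantom.voxel_size,
            "activity_sum": self.phantom.total_activity(),
        }, sort_keys=True, default=str)
        return {"seed": self.seed,
                "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16]}


def generate_acquisition(spec: AcquisitionSpec,
                         library: MaterialLibrary | None = None
                         ) -> EnergySpectrum:
    """Poisson counts: mean = live_time x detector-response(projection).

    Reproducible given the spec's seed; live_time -> 0 yields all-zero
    counts.
    """
    rate = project(spec.phantom, spec.camera, energies=spec.energy_edges,
                   pixels=spec.pixels, library=library)
    rate = apply_detector_response(rate, spec.camera, library=library)
    mean = rate.values * rate.bin_widths * spec.live_time
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(mean)
    return EnergySpectrum(pixels=rate.pixels, bin_edges=rate.bin_edges,
                          values=counts.astype(float), kind="counts")


def reference_peak_spectrum(peak_kev: float = 140.5, fwhm_kev: float = 14.0,
                            total_counts: float = 1e4,
                            bin_edges: np.ndarray | None = None,
                            rng: np.random.Generator | None = None):
    """Synthetic reference-source photopeak spectrum for calibration tests.

    A Gaussian photopeak (optionally Poisson-fluctuated when an rng is
    given) on the given bin grid; stands in for a measured Tc-99m block
    spectrum.
    """
    from .calibration import ReferenceSpectrum

    if bin_edges is None:
        bin_edges = np.arange(80.0, 201.0, 1.0)
    centers = (bin_edges[:-1] + bin_edges[1:]) / 2
    sigma = fwhm_kev / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    shape = np.exp(-0.5 * ((centers - peak_kev) / sigma) ** 2)
    counts = total_counts * shape / shape.sum()
    if rng is not None:
        counts = rng.poisson(counts).astype(float)
    return ReferenceSpectrum(bin_edges=np.asarray(bin_edges, dtype=float),
                             counts=counts, nominal_peak=peak_kev)
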