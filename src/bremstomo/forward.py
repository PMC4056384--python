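"""Energy-resolved bremsstrahlung forward projector and detector response.

For an ideal stationary camera above a water-equivalent patient, the
count-rate density recorded at energy E in pixel (x, y) is

    c(x, y, E) = a(E) * integral_0^inf A(r(l)) G(r(l))
                 exp(-mu(E) * (l - lp(x, y))) dl,

with r(l) the collimator line of response, A the Y-90 activity, G the
geometric efficiency, a(E) the bremsstrahlung yield in water, mu(E) the
water attenuation coefficient, and lp the LOR parameter at the patient
surface facing the collimator.  Because mu(E) is bijective for water,
the normalized projection C = c exp(-mu(E) lp) / a(E), re-parameterized
from E to mu, is the Laplace transform in depth of the effective profile
Abar(l) = A*G -- the recorded energy encodes source depth.

The projector performs exact voxel path-length (Siddon-style) ray
traversal with per-material attenuation line integrals (air is
attenuation-free but depth-advancing); for a homogeneous-water phantom
this reduces exactly to the mu(E)*(l - lp) factor of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import ndtr

from .geometry import Collimator, LineOfResponse, geometric_efficiency, \
    parallel_lor, pinhole_lor
from .laplace import MuSpectrum
from .physics import MaterialLibrary, default_library

__all__ = [
    "Phantom",
    "CameraModel",
    "EnergySpectrum",
    "NormalizedSpectrum",
    "ray_segments",
    "surface_depth",
    "water_equivalent_depth",
    "project",
    "normalize",
    "rebin_to_mu",
    "apply_detector_response",
]

AIR_NAME = "air"
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Phantom:
    """Voxelized activity and medium grids on a common lattice.

    activity: Bq per voxel, shape (nx, ny, nz); medium: integer code per
    voxel indexing `medium_names` (code for "air" is non-attenuating).
    origin is the coordinate (cm) of the low corner of voxel (0, 0, 0);
    the z axis points away from the detector.
    """

    activity: np.ndarray
    medium: np.ndarray
    medium_names: tuple[str, ...]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        med = np.asarray(self.medium, dtype=np.int16)
        object.__setattr__(self, "activity", act)
        object.__setattr__(self, "medium", med)
        if act.shape != med.shape or act.ndim != 3:
            raise ValueError("activity and medium grids must be congruent 3-D")
        if np.any(act < 0):
            raise ValueError("activity must be nonnegative")
        if med.min() < 0 or med.max() >= len(self.medium_names):
            raise ValueError("medium codes outside medium_names")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.activity.shape

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + np.asarray(self.shape) * np.asarray(self.voxel_size)
        return lo, hi

    def total_activity(self) -> float:
        return float(self.activity.sum())


@dataclass(frozen=True)
class CameraModel:
    """Collimator + crystal + energy response + acquisition window.

    resolution_r parameterizes the energy resolution as
    FWHM(E) = r * sqrt(E * reference_energy); r = 0 is an ideal camera
    (the assumption under which the Laplace depth encoding is exact).
    crystal=None means unit intrinsic efficiency.
    """

    collimator: Collimator
    crystal: "object | None" = None          # CrystalSlab; avoids import cycle
    resolution_r: float = 0.0
    reference_energy: float = 511.0
    window: tuple[float, float] = (50.0, 350.0)
    pixel_pitch: float = 0.5
    extent: tuple[float, float] = (45.0, 25.0)

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("window must satisfy E_lo < E_hi")
        if self.resolution_r < 0:
            raise ValueError("resolution r must be nonnegative")

    def pixel_centers(self) -> np.ndarray:
        """(npix, 2) pixel-center coordinates; centers at
        (i + 0.5) * pitch - extent / 2."""
        nx = int(round(self.extent[0] / self.pixel_pitch))
        ny = int(round(self.extent[1] / self.pixel_pitch))
        xs = (np.arange(nx) + 0.5) * self.pixel_pitch - self.extent[0] / 2
        ys = (np.arange(ny) + 0.5) * self.pixel_pitch - self.extent[1] / 2
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    def lor(self, x: float, y: float) -> LineOfResponse:
        if self.collimator.kind == "parallel":
            return parallel_lor(x, y)
        return pinhole_lor(x, y, self.collimator.focal_length)

    def energy_bin_edges(self, bin_width: float = 2.0) -> np.ndarray:
        lo, hi = self.window
        n = max(1, int(round((hi - lo) / bin_width)))
        return np.linspace(lo, hi, n + 1)

    def fwhm(self, energy) -> np.ndarray:
        return self.resolution_r * np.sqrt(
            np.asarray(energy, dtype=float) * self.reference_energy)


@dataclass(frozen=True)
class EnergySpectrum:
    """Per-pixel energy spectra on shared bin edges.

    values has shape (npix, nbins); kind is "rate" (count-rate density,
    1/s/keV, as produced by the projector) or "counts" (integer counts
    per bin, as produced by an acquisition).
    """

    pixels: np.ndarray        # (npix, 2) detector-plane coordinates
    bin_edges: np.ndarray     # (nbins + 1,), strictly increasing keV
    values: np.ndarray        # (npix, nbins), >= 0
    kind: str = "rate"

    def __post_init__(self) -> None:
        px = np.atleast_2d(np.asarray(self.pixels, dtype=float))
        edges = np.asarray(self.bin_edges, dtype=float)
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "values", vals)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if vals.shape != (px.shape[0], edges.size - 1):
            raise ValueError("values shape must be (npix, nbins)")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be nonnegative")

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def total(self) -> np.ndarray:
        """Total per pixel: counts, or rate integrated over energy."""
        if self.kind == "counts":
            return self.values.sum(axis=1)
        return (self.values * self.bin_widths).sum(axis=1)


@dataclass(frozen=True)
class NormalizedSpectrum:
    """C(x, y, E) per pixel: attenuation-unfolded, yield-normalized."""

    pixels: np.ndarray
    energies: np.ndarray
    values: np.ndarray  # (npix, nE)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")


# ---------------------------------------------------------------------------
# ray traversal


def ray_segments(phantom: Phantom, lor: LineOfResponse,
                 l_max: float | None = None):
    """Exact voxel intersections of a LOR with the phantom lattice.

    Returns (indices, l_in, l_out): voxel indices (m, 3) and the entry /
    exit values of the LOR parameter for each traversed voxel, ordered by
    increasing l.  Siddon-style: parametric crossings of all lattice
    planes, no sampling.
    """
    p0 = lor.origin
    u = lor.direction
    lo, hi = phantom.bounds
    t0 = 0.0
    t1 = np.inf if l_max is None else float(l_max)
    for a in range(3):
        if abs(u[a]) < 1e-12:
            if not (lo[a] < p0[a] < hi[a]):
                return (np.empty((0, 3), dtype=int), np.empty(0), np.empty(0))
        else:
            ta = (lo[a] - p0[a]) / u[a]
            tb = (hi[a] - p0[a]) / u[a]
            t0 = max(t0, min(ta, tb))
            t1 = min(t1, max(ta, tb))
    if t1 <= t0:
        return (np.empty((0, 3), dtype=int), np.empty(0), np.empty(0))

    crossings = [np.array([t0, t1])]
    vx = np.asarray(phantom.voxel_size)
    for a in range(3):
        if abs(u[a]) < 1e-12:
            continue
        planes = lo[a] + vx[a] * np.arange(phantom.shape[a] + 1)
        t = (planes - p0[a]) / u[a]
        crossings.append(t[(t > t0) & (t < t1)])
    ts = np.unique(np.concatenate(crossings))
    dl = np.diff(ts)
    keep = dl > 1e-12
    l_in, l_out = ts[:-1][keep], ts[1:][keep]
    mids = (l_in + l_out) / 2
    pts = p0 + mids[:, None] * u
    idx = np.floor((pts - lo) / vx).astype(int)
    idx = np.clip(idx, 0, np.asarray(phantom.shape) - 1)
    return idx, l_in, l_out


def surface_depth(phantom: Phantom, lor: LineOfResponse) -> float:
    """lp: smallest l at which the LOR enters a non-air voxel (inf = miss)."""
    idx, l_in, _ = ray_segments(phantom, lor)
    if idx.shape[0] == 0:
        return np.inf
    air_code = _air_code(phantom)
    codes = phantom.medium[idx[:, 0], idx[:, 1], idx[:, 2]]
    hits = np.nonzero(codes != air_code)[0]
    if hits.size == 0:
        return np.inf
    return float(l_in[hits[0]])


def _air_code(phantom: Phantom) -> int:
    try:
        return phantom.medium_names.index(AIR_NAME)
    except ValueError:
        return -1  # no air in this phantom


def water_equivalent_depth(phantom: Phantom, lor: LineOfResponse,
                           l_stop: float,
                           library: MaterialLibrary | None = None,
                           reference_energy: float = 200.0) -> float:
    """Water-equivalent attenuation depth from the surface to l_stop.

    Sum over traversed non-air materials of path * mu_mat / mu_water at
    the reference energy; equals l_stop - lp for water-only phantoms.
    Useful to interpret depth estimates in mixed-medium phantoms.
    """
    lib = library or default_library()
    idx, l_in, l_out = ray_segments(phantom, lor, l_max=l_stop)
    if idx.shape[0] == 0:
        return 0.0
    air_code = _air_code(phantom)
    codes = phantom.medium[idx[:, 0], idx[:, 1], idx[:, 2]]
    mu_w = lib.water_mu(reference_energy)
    depth = 0.0
    for code in np.unique(codes):
        if code == air_code:
            continue
        path = ((l_out - l_in)[codes == code]).sum()
        mu = lib.attenuation_coefficient(phantom.medium_names[code],
                                         reference_energy)
        depth += path * mu / mu_w
    return float(depth)


# ---------------------------------------------------------------------------
# projection


def project(phantom: Phantom, camera: CameraModel,
            energies: np.ndarray | None = None,
            pixels: Sequence[tuple[float, float]] | None = None,
            library: MaterialLibrary | None = None) -> EnergySpectrum:
    """Geometric (unscattered, unblurred) count-rate spectra per pixel.

    energies are bin edges (default: the camera window at 2 keV bins);
    values are the count-rate density c(x, y, E) evaluated at bin
    centers.  Linear in the activity grid.  Attenuation accrues only in
    non-air media beyond the patient surface, per material, by exact
    chord lengths.
    """
    lib = library or default_library()
    edges = np.asarray(energies, dtype=float) if energies is not None \
        else camera.energy_bin_edges()
    centers = (edges[:-1] + edges[1:]) / 2
    lo_tab, hi_tab = lib.table("water").energy_range
    if centers[0] < lo_tab or centers[-1] > hi_tab:
        raise ValueError(
            f"energy grid outside attenuation tables [{lo_tab}, {hi_tab}] keV")

    pix = np.atleast_2d(np.asarray(
        pixels if pixels is not None else camera.pixel_centers(), dtype=float))
    air_code = _air_code(phantom)
    yields = lib.brems_yield(centers)

    # per-material mu(E) for the non-air media present
    codes_present = [c for c in np.unique(phantom.medium) if c != air_code]
    mu_by_code = {c: lib.attenuation_coefficient(
        phantom.medium_names[c], centers) for c in codes_present}

    out = np.zeros((pix.shape[0], centers.size))
    f = camera.collimator.focal_length if camera.collimator.kind == "pinhole" \
        else 0.0
    for i, (px, py) in enumerate(pix):
        lor = camera.lor(px, py)
        idx, l_in, l_out = ray_segments(phantom, lor)
        if idx.shape[0] == 0:
            continue
        codes = phantom.medium[idx[:, 0], idx[:, 1], idx[:, 2]]
        act = phantom.activity[idx[:, 0], idx[:, 1], idx[:, 2]]
        if not np.any(act > 0):
            continue
        if camera.collimator.kind == "pinhole":
            # subdivide chords near the aperture: G ~ 1/h^2 curves too
            # fast there for single-midpoint quadrature
            h_mid = np.abs((l_in + l_out) / 2)
            m = np.maximum(1, np.ceil(
                (l_out - l_in) / (0.1 * np.maximum(h_mid, 0.5)))).astype(int)
            codes = np.repeat(codes, m)
            act = np.repeat(act, m)
            sub_dl = np.repeat((l_out - l_in) / m, m)
            offsets = (np.arange(m.sum())
                       - np.repeat(np.cumsum(m) - m, m) + 0.5)
            l_in = np.repeat(l_in, m) + (offsets - 0.5) * sub_dl
            l_out = l_in + sub_dl
        dl = l_out - l_in
        mids = (l_in + l_out) / 2
        pts = lor.origin + mids[:, None] * lor.direction
        # attenuation path per material up to each segment midpoint
        atten_exp = np.zeros((centers.size, mids.size))
        for c in codes_present:
            in_mat = codes == c
            seg_path = np.where(in_mat, dl, 0.0)
            path_mid = np.cumsum(seg_path) - seg_path / 2
            atten_exp += np.outer(mu_by_code[c], path_mid)
        hot = act > 0
        if camera.collimator.kind == "pinhole":
            hot &= pts[:, 2] > f  # voxels behind the aperture are blocked
        if not hot.any():
            continue
        g = geometric_efficiency(camera.collimator, pts[hot])
        w = act[hot] * np.atleast_1d(g) * dl[hot]
        out[i] = yields * (np.exp(-atten_exp[:, hot]) @ w)
    return EnergySpectrum(pixels=pix, bin_edges=edges, values=out, kind="rate")


def normalize(spectrum: EnergySpectrum, lp,
              library: MaterialLibrary | None = None,
              efficiency: Callable | None = None) -> NormalizedSpectrum:
    """C(x, y, E) = c(x, y, E) exp(-mu(E) lp) / a(E), per pixel.

    Unfolds the surface-to-camera attenuation offset and the
    bremsstrahlung yield so that the result is the pure Laplace forward
    of the depth profile.  If `efficiency` (ε(E), e.g. the camera's
    intrinsic full-energy efficiency) is given it is divided out as
    well.  Count spectra are first converted to densities with the bin
    widths; lp must be finite for every pixel.
    """
    lib = library or default_library()
    centers = spectrum.bin_centers
    a = np.asarray(lib.brems_yield(centers), dtype=float)
    if np.any(a <= 0):
        raise ValueError(
            "bremsstrahlung yield vanishes on the energy grid "
            "(beyond the beta endpoint): normalization undefined")
    lp_arr = np.broadcast_to(np.asarray(lp, dtype=float),
                             (spectrum.pixels.shape[0],))
    if not np.all(np.isfinite(lp_arr)):
        raise ValueError("lp must be finite for every normalized pixel")
    vals = spectrum.values.astype(float)
    if spectrum.kind == "counts":
        vals = vals / spectrum.bin_widths
    mu = np.asarray(lib.water_mu(centers), dtype=float)
    c = vals * np.exp(-np.outer(lp_arr, mu)) / a
    if efficiency is not None:
        c = c / np.asarray(efficiency(centers), dtype=float)
    return NormalizedSpectrum(pixels=spectrum.pixels, energies=centers,
                              values=c)


def rebin_to_mu(norm: NormalizedSpectrum,
                library: MaterialLibrary | None = None) -> list[MuSpectrum]:
    """C_hat(x, y, mu) = C(x, y, E(mu)): relabel the energy axis by the
    water attenuation coefficient.  The mu grid ascends (energy axis
    reversed); one MuSpectrum per pixel."""
    lib = library or default_library()
    mu = np.asarray(lib.water_mu(norm.energies), dtype=float)
    order = np.argsort(mu)
    return [MuSpectrum(mu=mu[order], values=norm.values[i, order],
                       pixel=tuple(norm.pixels[i]))
            for i in range(norm.pixels.shape[0])]


def apply_detector_response(spectrum: EnergySpectrum, camera: CameraModel,
                            efficiency: Callable | None = None,
                            library: MaterialLibrary | None = None
                            ) -> EnergySpectrum:
    """Intrinsic efficiency x Gaussian energy blur x acquisition window.

    Efficiency defaults to the analytic full-energy proxy of the camera
    crystal (1 - exp(-mu t)), or unity without a crystal.  The blur is a
    stochastic matrix built from Gaussian CDFs with energy-dependent
    FWHM(E) = r sqrt(E E_ref); outer bins absorb the tails so the blur
    conserves total counts exactly (before windowing).  Bins whose
    centers fall outside the window are zeroed.
    """
    lib = library or default_library()
    centers = spectrum.bin_centers
    edges = spectrum.bin_edges
    vals = spectrum.values.astype(float)

    if efficiency is not None:
        eps = np.asarray(efficiency(centers), dtype=float)
    elif camera.crystal is not None:
        eps = np.asarray(lib.absorption_probability(
            camera.crystal.material, camera.crystal.thickness, centers))
    else:
        eps = np.ones_like(centers)
    vals = vals * eps

    if camera.resolution_r > 0:
        sigma = camera.fwhm(centers) * FWHM_TO_SIGMA
        # blur[i, j]: fraction of bin j landing in bin i; columns sum to 1
        z = (edges[:, None] - centers[None, :]) / sigma[None, :]
        cdf = ndtr(z)
        cdf[0, :] = 0.0
        cdf[-1, :] = 1.0
        blur = np.diff(cdf, axis=0)
        vals = vals @ blur.T

    lo, hi = camera.window
    vals = np.where((centers >= lo) & (centers <= hi), vals, 0.0)
    return EnergySpectrum(pixels=spectrum.pixels, bin_edges=edges,
                          values=vals, kind=spectrum.kind)
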