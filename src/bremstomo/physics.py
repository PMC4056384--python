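"""Physical-constant tables and evaluators.

Mass attenuation coefficients per material (total / photoelectric /
incoherent channels, bundled as CSV package data on a 30 keV - 3 MeV
logarithmic grid), the bijective water mu <-> E mapping that underlies
energy-resolved depth encoding, and the relative bremsstrahlung x-ray
yield spectrum a(E) of Y-90 in water.

Conventions: energies in keV, lengths in cm, linear attenuation mu in
1/cm, mass attenuation mu/rho in cm^2/g.  The "total" channel excludes
coherent (Rayleigh) scattering -- the narrow-beam correction convention
under which water mu(E) is strictly decreasing and the energy->depth
mapping is bijective.  Interpolation between grid knots is log-log
linear, so a query at a knot returns the knot value exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Material",
    "AttenuationTable",
    "BremsYield",
    "MaterialLibrary",
    "default_library",
    "attenuation_coefficient",
    "energy_from_mu",
    "brems_yield",
    "absorption_probability",
]

_CHANNELS = {
    "total": "mu_over_rho_total",
    "photoelectric": "mu_over_rho_pe",
    "incoherent": "mu_over_rho_incoh",
}

# canonical lowercase names plus field-standard spellings
_ALIASES = {
    "h2o": "water",
    "pmma": "perpex",
    "perspex": "perpex",
    "pb": "lead",
    "w": "tungsten",
    "sn": "tin",
}


@dataclass(frozen=True)
class Material:
    """A homogeneous material: name, bulk density, elemental make-up."""

    name: str
    density: float  # g/cm^3
    composition: Mapping[str, float]  # element -> mass fraction

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, expected 1")


@dataclass(frozen=True)
class AttenuationTable:
    """Per-material mu/rho vs energy with log-log interpolation."""

    material: Material
    energies: np.ndarray  # keV, strictly ascending
    mu_over_rho_total: np.ndarray
    mu_over_rho_photoelectric: np.ndarray
    mu_over_rho_incoherent: np.ndarray
    _log_e: np.ndarray = field(init=False, repr=False)
    _log_mu: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        for arr in (self.mu_over_rho_total, self.mu_over_rho_photoelectric,
                    self.mu_over_rho_incoherent):
            if np.any(arr <= 0):
                raise ValueError("attenuation coefficients must be positive")
        object.__setattr__(self, "_log_e", np.log(self.energies))
        object.__setattr__(self, "_log_mu", {
            "total": np.log(self.mu_over_rho_total),
            "photoelectric": np.log(self.mu_over_rho_photoelectric),
            "incoherent": np.log(self.mu_over_rho_incoherent),
        })

    @property
    def energy_range(self) -> tuple[float, float]:
        return float(self.energies[0]), float(self.energies[-1])

    def mass_attenuation(self, energy, channel: str = "total") -> np.ndarray:
        """mu/rho (cm^2/g), log-log interpolated; exact at grid knots."""
        if channel not in _CHANNELS:
            raise ValueError(f"unknown channel {channel!r}")
        e = np.asarray(energy, dtype=float)
        lo, hi = self.energy_range
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy outside table range [{lo}, {hi}] keV for "
                f"{self.material.name}")
        out = np.exp(np.interp(np.log(e), self._log_e, self._log_mu[channel]))
        return out if out.ndim else float(out)

    def linear_attenuation(self, energy, channel: str = "total"):
        """mu (1/cm) = density * mu/rho."""
        return self.material.density * self.mass_attenuation(energy, channel)


@dataclass(frozen=True)
class BremsYield:
    """Relative bremsstrahlung x-ray yield a(E) in water per Y-90 decay.

    Zero at and above the beta endpoint e_max.  The absolute scale is
    arbitrary (a(E) cancels in the normalized projection), bundled with
    unit integral.
    """

    energies: np.ndarray
    yield_per_kev: np.ndarray
    e_max: float = 2300.0

    def __post_init__(self) -> None:
        if np.any(self.yield_per_kev < 0):
            raise ValueError("yield must be nonnegative")
        if np.any(self.yield_per_kev[self.energies >= self.e_max] != 0):
            raise ValueError("yield must vanish at and above e_max")

    def __call__(self, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        if np.any(e < 0):
            raise ValueError("energy must be nonnegative")
        out = np.where(
            e >= self.e_max, 0.0,
            np.interp(e, self.energies, self.yield_per_kev,
                      left=self.yield_per_kev[0], right=0.0))
        return out if out.ndim else float(out)


class MaterialLibrary:
    """Registry of bundled materials, attenuation tables and yield spectrum.

    By default loads the CSV/JSON package data; user tables can be
    registered or substituted via :meth:`register`.
    """

    def __init__(self, data_dir=None):
        if data_dir is None:
            data_dir = resources.files("bremstomo") / "data"
        self._dir = data_dir
        with (data_dir / "materials.json").open() as fh:
            self._manifest = json.load(fh)
        self._tables: dict[str, AttenuationTable] = {}
        yld = pd.read_csv(data_dir / "brems_yield_y90.csv")
        self.brems = BremsYield(
            energies=yld["energy_keV"].to_numpy(),
            yield_per_kev=yld["yield_per_decay_per_keV"].to_numpy(),
            e_max=self._manifest.get("brems_endpoint_keV", 2300.0),
        )
        self.tc99m_photopeak_kev: float = self._manifest.get(
            "tc99m_photopeak_keV", 140.5)
        self._water_inverse = None

    # -- lookup ----------------------------------------------------------
    def canonical_name(self, material) -> str:
        name = material.name if isinstance(material, Material) else str(material)
        key = name.lower()
        key = _ALIASES.get(key, key)
        if key not in self._manifest["materials"] and key not in self._tables:
            raise KeyError(f"unknown material {name!r}")
        return key

    def material(self, name) -> Material:
        return self.table(name).material

    def table(self, material) -> AttenuationTable:
        key = self.canonical_name(material)
        if key not in self._tables:
            entry = self._manifest["materials"][key]
            df = pd.read_csv(self._dir / entry["table"])
            self._tables[key] = AttenuationTable(
                material=Material(key, entry["density_g_cm3"],
                                  entry["composition"]),
                energies=df["energy_keV"].to_numpy(),
                mu_over_rho_total=df["mu_over_rho_total"].to_numpy(),
                mu_over_rho_photoelectric=df["mu_over_rho_pe"].to_numpy(),
                mu_over_rho_incoherent=df["mu_over_rho_incoh"].to_numpy(),
            )
        return self._tables[key]

    def register(self, table: AttenuationTable) -> None:
        self._tables[table.material.name.lower()] = table
        self._water_inverse = None

    @property
    def names(self) -> list[str]:
        return sorted(set(self._manifest["materials"]) | set(self._tables))

    # -- operations ------------------------------------------------------
    def attenuation_coefficient(self, material, energy,
                                channel: str = "total"):
        """Linear attenuation mu (1/cm) of `material` at `energy` keV."""
        return self.table(material).linear_attenuation(energy, channel)

    def water_mu(self, energy):
        return self.attenuation_coefficient("water", energy)

    def energy_from_mu(self, mu):
        """Invert the bijective water mu(E) (total channel) -> E in keV."""
        if self._water_inverse is None:
            tab = self.table("water")
            mu_grid = tab.material.density * tab.mu_over_rho_total
            if np.any(np.diff(mu_grid) >= 0):
                raise ValueError("water table is not strictly decreasing")
            # ascending in mu = descending in E
            self._water_inverse = (np.log(mu_grid[::-1]),
                                   np.log(tab.energies[::-1]))
        log_mu_grid, log_e_grid = self._water_inverse
        m = np.asarray(mu, dtype=float)
        if np.any(m < np.exp(log_mu_grid[0])) or np.any(m > np.exp(log_mu_grid[-1])):
            raise ValueError(
                "mu outside the attainable water range "
                f"[{np.exp(log_mu_grid[0]):.4g}, {np.exp(log_mu_grid[-1]):.4g}] 1/cm")
        out = np.exp(np.interp(np.log(m), log_mu_grid, log_e_grid))
        return out if out.ndim else float(out)

    def water_mu_range(self) -> tuple[float, float]:
        tab = self.table("water")
        mu = tab.material.density * tab.mu_over_rho_total
        return float(mu[-1]), float(mu[0])

    def brems_yield(self, energy):
        """a(E): relative bremsstrahlung yield in water at `energy` keV."""
        return self.brems(energy)

    def absorption_probability(self, material, thickness: float, energy):
        """Analytic attenuation probability 1 - exp(-mu_total * t).

        The table-derived counterpart of the full-energy Monte Carlo: the
        probability that a photon interacts at all inside the slab.
        """
        t = np.asarray(thickness, dtype=float)
        if np.any(t < 0):
            raise ValueError("thickness must be nonnegative")
        mu = self.attenuation_coefficient(material, energy)
        return -np.expm1(-mu * t)


_default_library: MaterialLibrary | None = None


def default_library() -> MaterialLibrary:
    global _default_library
    if _default_library is None:
        _default_library = MaterialLibrary()
    return _default_library


def attenuation_coefficient(material, energy, channel: str = "total"):
    return default_library().attenuation_coefficient(material, energy, channel)


def energy_from_mu(mu):
    return default_library().energy_from_mu(mu)


def brems_yield(energy):
    return default_library().brems_yield(energy)


def absorption_probability(material, thickness, energy):
    return default_library().absorption_probability(material, thickness, energy)
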