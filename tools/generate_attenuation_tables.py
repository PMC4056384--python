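"""Generate the bundled physical-constant tables under src/bremstomo/data/.

Run from the repository root:

    python tools/generate_attenuation_tables.py

Construction
------------
Incoherent (Compton) mass attenuation is computed exactly from the total
Klein-Nishina cross section on free electrons times the electron density
N_A * (Z/A)_eff.  Electron binding (incoherent scattering function) is
neglected; the error is <2% above 50 keV for the materials bundled here.

Photoelectric mass attenuation per element is A_Z * S(E): a per-element
amplitude at 511 keV times a shared piecewise log-log power-law shape.
The shape exponents are fitted to lead (NIST grid values, photoelectric
isolated by subtracting Klein-Nishina incoherent and coherent estimates);
the amplitudes are anchored to standard detector-physics data:

  Pb   0.0790 cm^2/g  (NIST 500-600 keV grid values)
  Bi   0.0843          BGO attenuation length 1.05 cm at 511 keV
  Gd   0.0406          GSO attenuation length 1.38 cm at 511 keV
  I    0.0200          NaI attenuation length 2.88 cm at 511 keV
  W    0.0590          NIST 500 keV total
  light elements       anchored to water photoelectric at 50 keV

K-edges inside the 30-3000 keV grid (I, Gd, W, Pb, Bi) are modelled as a
downward jump (division by the literature jump ratio) below the edge; the
grid carries a straddling pair of knots at each edge.

Totals are photoelectric + incoherent: coherent (Rayleigh) scattering is
excluded by convention (narrow-beam correction, see docs/methods.md) and
pair production is out of scope, so high-Z totals above 1.2 MeV are below
literature values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "bremstomo" / "data"

AVOGADRO = 6.02214076e23  # 1/mol
ELECTRON_REST_KEV = 510.99895
R_E2 = 7.94079e-26  # classical electron radius squared, cm^2

# element: (Z, atomic mass g/mol, photoelectric mu/rho at 511 keV cm^2/g,
#           shape family, K-edge keV or None, edge jump ratio)
ELEMENTS = {
    "H": (1, 1.008, 1.0e-8, "light", None, None),
    "C": (6, 12.011, 1.48e-5, "light", None, None),
    "N": (7, 14.007, 2.54e-5, "light", None, None),
    "O": (8, 15.999, 4.06e-5, "light", None, None),
    "Na": (11, 22.990, 1.19e-4, "light", None, None),
    "Si": (14, 28.085, 2.87e-4, "light", None, None),
    "Ge": (32, 72.630, 4.5e-3, "heavy", None, None),  # K-edge 11 keV, below grid
    "Cd": (48, 112.414, 1.52e-2, "heavy", None, None),  # K-edge 26.7 keV, below grid
    "Sn": (50, 118.710, 1.70e-2, "heavy", None, None),  # K-edge 29.2 keV, below grid
    "I": (53, 126.904, 2.00e-2, "heavy", 33.17, 5.9),
    "Gd": (64, 157.25, 4.06e-2, "heavy", 50.24, 5.6),
    "W": (74, 183.84, 5.90e-2, "heavy", 69.53, 4.9),
    "Pb": (82, 207.20, 7.90e-2, "heavy", 88.00, 4.8),
    "Bi": (83, 208.980, 8.43e-2, "heavy", 90.53, 4.7),
}

# material: (density g/cm^3, {element: mass fraction})
MATERIALS = {
    "water": (1.000, {"H": 0.1119, "O": 0.8881}),
    "air": (1.205e-3, {"N": 0.7670, "O": 0.2330}),
    "perpex": (1.190, {"H": 0.080538, "C": 0.599848, "O": 0.319614}),
    "nai": (3.670, {"Na": 0.1534, "I": 0.8466}),
    "bgo": (7.130, {"Bi": 0.6710, "Ge": 0.1749, "O": 0.1541}),
    "gso": (6.710, {"Gd": 0.7442, "Si": 0.0665, "O": 0.1893}),
    "cdwo4": (7.900, {"Cd": 0.3120, "W": 0.5103, "O": 0.1777}),
    "lead": (11.340, {"Pb": 1.0}),
    "tungsten": (19.300, {"W": 1.0}),
    "tin": (7.310, {"Sn": 1.0}),
}

# piecewise power-law exponents (break keV, exponent on the segment below it)
SHAPES = {
    "heavy": [(300.0, 2.62), (600.0, 2.47), (1200.0, 2.05), (3001.0, 1.55)],
    "light": [(150.0, 3.10), (600.0, 2.75), (3001.0, 2.10)],
}
ANCHOR_KEV = 511.0


def klein_nishina_total(energy_kev: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross section per electron, cm^2."""
    k = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    t = 1.0 + 2.0 * k
    sigma = 2.0 * np.pi * R_E2 * (
        (1.0 + k) / k**2 * (2.0 * (1.0 + k) / t - np.log(t) / k)
        + np.log(t) / (2.0 * k)
        - (1.0 + 3.0 * k) / t**2
    )
    return sigma


def shape_factor(energy_kev: np.ndarray, family: str) -> np.ndarray:
    """S(E) with S(511)=1, piecewise log-log power law."""
    segs = SHAPES[family]

    def log_s(e):
        # integrate the piecewise slope from the anchor to e
        out = 0.0
        lo = min(e, ANCHOR_KEV)
        hi = max(e, ANCHOR_KEV)
        prev = 30.0
        for brk, n in segs:
            a, b = max(prev, lo), min(brk, hi)
            if b > a:
                out += n * np.log(b / a)
            prev = brk
        return out if e < ANCHOR_KEV else -out

    return np.exp([log_s(float(e)) for e in np.atleast_1d(energy_kev)])


def photoelectric(element: str, energy_kev: np.ndarray) -> np.ndarray:
    _, _, amp, family, edge, jump = ELEMENTS[element]
    pe = amp * shape_factor(energy_kev, family)
    if edge is not None:
        pe = np.where(np.atleast_1d(energy_kev) < edge, pe / jump, pe)
    return pe


def energy_grid() -> np.ndarray:
    grid = set(np.geomspace(30.0, 3000.0, 120))
    grid.update([50.0, 100.0, 140.5, 150.0, 200.0, 300.0, 350.0, 400.0,
                 511.0, 600.0, 662.0, 800.0, 1000.0, 1500.0, 2000.0,
                 2300.0, 3000.0])
    for el in ("I", "Gd", "W", "Pb", "Bi"):
        edge = ELEMENTS[el][4]
        grid.update([edge * (1 - 1e-4), edge * (1 + 1e-4)])
    return np.array(sorted(grid))


def build_material_table(name: str, grid: np.ndarray) -> pd.DataFrame:
    _, fractions = MATERIALS[name]
    z_over_a = sum(w * ELEMENTS[el][0] / ELEMENTS[el][1] for el, w in fractions.items())
    incoh = AVOGADRO * z_over_a * klein_nishina_total(grid)
    pe = np.zeros_like(grid)
    for el, w in fractions.items():
        pe += w * photoelectric(el, grid)
    return pd.DataFrame({
        "energy_keV": grid,
        "mu_over_rho_total": pe + incoh,
        "mu_over_rho_pe": pe,
        "mu_over_rho_incoh": incoh,
    })


def build_brems_yield(e_max: float = 2300.0) -> pd.DataFrame:
    """Relative bremsstrahlung x-ray yield spectrum a(E) in water for Y-90.

    Kramers thin-target intensity (proportional to (T-E)/E per electron of
    kinetic energy T) folded over an allowed-shape beta spectrum with the
    Y-90 endpoint; normalized to unit integral.  a(E) cancels in the
    normalized projection C, so only positivity and support matter.
    """
    t_grid = np.linspace(1.0, e_max, 4000)
    w = 1.0 + t_grid / ELECTRON_REST_KEV
    w0 = 1.0 + e_max / ELECTRON_REST_KEV
    p = np.sqrt(np.maximum(w**2 - 1.0, 0.0))
    beta = p * w * (w0 - w) ** 2  # allowed shape, screening folded into shape only
    beta /= np.trapezoid(beta, t_grid)

    e_grid = np.unique(np.concatenate([
        np.geomspace(1.0, e_max, 300), [50.0, 350.0, 511.0, e_max]]))
    yield_vals = np.empty_like(e_grid)
    for i, e in enumerate(e_grid):
        mask = t_grid > e
        yield_vals[i] = np.trapezoid(beta[mask] * (t_grid[mask] - e) / e,
                                     t_grid[mask]) if mask.any() else 0.0
    yield_vals[e_grid >= e_max] = 0.0
    norm = np.trapezoid(yield_vals, e_grid)
    return pd.DataFrame({"energy_keV": e_grid,
                         "yield_per_decay_per_keV": yield_vals / norm})


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    grid = energy_grid()
    manifest = {
        "energy_min_keV": float(grid[0]),
        "energy_max_keV": float(grid[-1]),
        "total_channel_convention": "photoelectric + incoherent (coherent excluded)",
        "brems_endpoint_keV": 2300.0,
        "tc99m_photopeak_keV": 140.5,
        "materials": {},
    }
    for name, (density, fractions) in MATERIALS.items():
        table = build_material_table(name, grid)
        table.to_csv(DATA_DIR / f"attenuation_{name}.csv", index=False,
                     float_format="%.10e")
        manifest["materials"][name] = {
            "density_g_cm3": density,
            "composition": fractions,
            "table": f"attenuation_{name}.csv",
        }
    build_brems_yield().to_csv(DATA_DIR / "brems_yield_y90.csv", index=False,
                               float_format="%.6e")
    with open(DATA_DIR / "materials.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    print(f"wrote tables for {len(MATERIALS)} materials, "
          f"{len(grid)} energy knots -> {DATA_DIR}")


if __name__ == "__main__":
    main()
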