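"""BGO temperature gain drift and reference-spectrum energy rescaling.

BGO light output falls by about 1.2% per kelvin, shifting the measured
energy scale between acquisitions.  The correction procedure mirrors
camera practice: record a Tc-99m reference spectrum (140.5 keV
photopeak) at thermal equilibrium, fit the photopeak before each
acquisition, and rescale recorded event energies by the ratio
nominal/measured peak.  Rescaling is linear through zero (a single gain
factor, no offset) -- the drift mechanism is multiplicative light
yield.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GainModel",
    "ReferenceSpectrum",
    "PeakFitError",
    "gain_factor",
    "fit_peak",
    "rescale_energies",
    "TC99M_PHOTOPEAK_KEV",
]

TC99M_PHOTOPEAK_KEV = 140.5  # standard nuclide datum, configurable per call


class PeakFitError(RuntimeError):
    """No usable photopeak in the requested fit window."""


@dataclass(frozen=True)
class GainModel:
    """Linear temperature gain model: factor = 1 + coefficient (T - T0).

    coefficient is the fractional light-yield change per kelvin
    (default -0.012, i.e. -1.2%/K for BGO); reference_temperature T0 in
    kelvin is where the reference spectra were recorded.
    """

    reference_temperature: float = 293.15
    coefficient: float = -0.012


def gain_factor(model: GainModel, temperature: float) -> float:
    """Relative gain at `temperature` (K); errors if the factor is <= 0."""
    factor = 1.0 + model.coefficient * (temperature
                                        - model.reference_temperature)
    if factor <= 0:
        raise ValueError(
            f"temperature {temperature} K drives the gain factor to "
            f"{factor:.3g} <= 0: outside the supported span")
    return factor


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Binned reference-source spectrum with a nominal photopeak energy."""

    bin_edges: np.ndarray
    counts: np.ndarray
    nominal_peak: float = TC99M_PHOTOPEAK_KEV

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if counts.size != edges.size - 1:
            raise ValueError("counts must have one entry per bin")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    @classmethod
    def from_events(cls, energies, bin_edges,
                    nominal_peak: float = TC99M_PHOTOPEAK_KEV
                    ) -> "ReferenceSpectrum":
        counts, edges = np.histogram(np.asarray(energies, dtype=float),
                                     bins=np.asarray(bin_edges, dtype=float))
        return cls(bin_edges=edges, counts=counts, nominal_peak=nominal_peak)


def _gaussian(x, amp, center, sigma):
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def fit_peak(spectrum: ReferenceSpectrum, window: tuple[float, float]) -> float:
    """Gaussian-fit centroid (keV) of the photopeak inside `window`.

    Falls within one bin of the discrete argmax for clean peaks.  Raises
    PeakFitError when the window holds no interior local maximum or the
    fit cannot converge.
    """
    centers = spectrum.bin_centers
    mask = (centers >= window[0]) & (centers <= window[1])
    if mask.sum() < 4:
        raise PeakFitError("fit window covers fewer than four bins")
    x = centers[mask]
    y = spectrum.counts[mask]
    imax = int(np.argmax(y))
    if imax in (0, x.size - 1) or y[imax] <= 0:
        raise PeakFitError("no interior local maximum in the fit window")
    half = y[imax] / 2
    above = np.nonzero(y >= half)[0]
    sigma0 = max((x[above[-1]] - x[above[0]]) / 2.355, np.diff(x).min())
    try:
        popt, _ = curve_fit(_gaussian, x, y,
                            p0=[y[imax], x[imax], sigma0], maxfev=5000)
    except RuntimeError as exc:
        raise PeakFitError(f"Gaussian fit failed: {exc}") from exc
    center = float(popt[1])
    if not (window[0] <= center <= window[1]):
        raise PeakFitError(f"fitted centroid {center:.1f} keV left the window")
    return center


def rescale_energies(events, measured_peak: float, nominal_peak: float
                     = TC99M_PHOTOPEAK_KEV) -> np.ndarray:
    """Gain-correct event energies by the factor nominal/measured peak."""
    if measured_peak <= 0:
        raise ValueError("measured peak must be positive")
    return np.asarray(events, dtype=float) * (nominal_peak / measured_peak)
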