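# Methods

`bremstomo` models an idealized energy-resolved bremsstrahlung camera for
⁹⁰Y liver radioembolization and implements the pieces needed to study it
end to end: physics tables, collimator geometry, the forward projector,
the Laplace-transform depth reconstruction, a scintillator-slab photon
Monte Carlo, and the prototype's temperature gain calibration.  This note
records the model, its assumptions, the numerical choices, and what the
bundled synthetic data do and do not establish.

## The depth-encoding model

⁹⁰Y emits no useful gamma line; imaging relies on the continuous
bremsstrahlung spectrum (endpoint 2.3 MeV) produced by the betas in
tissue.  For an ideal camera–collimator (no scatter, penetration or
fluorescence; perfect spatial and energy resolution) above a
water-equivalent patient, the count-rate density at energy E in pixel
(x, y) is

    c(x, y, E) = ∫₀^∞ a(E) A(r(l)) G(r(l)) e^{−μ(E)(l−l_p(x,y))} dl ,

where r(l) is the collimator line of response (LOR), A the activity
concentration, G the collimator's geometric efficiency, a(E) the
bremsstrahlung yield per decay in water, μ(E) the total attenuation
coefficient of water, and l_p the LOR parameter at the patient surface
facing the collimator.  Two LOR parameterizations are provided:
parallel-hole, r(l) = (x, y, l), and pinhole with aperture at (0, 0, F),

    x′(l) = −l x / s,  y′(l) = −l y / s,  z′(l) = F + l F / s ,
    s = √(F² + x² + y²) .

In both cases |dr/dl| = 1 exactly (the s factors cancel), so l is
Euclidean arclength from the crystal plane (parallel) or the aperture
(pinhole).

Defining the normalized spectrum C = c·e^{−μ(E) l_p}/a(E) and exploiting
that μ(E) is strictly decreasing (hence invertible) for water, the
re-parameterized projection

    Ĉ(x, y, μ) = ∫₀^∞ Ā(l) e^{−μ l} dl ,   Ā(l) = A(r(l)) G(r(l)) ,

is the Laplace transform in depth of the effective activity profile:
the recorded energy plays the role of the rotation angle of conventional
SPECT.  The additive null-function ambiguity of the inverse transform
(Lerch) is taken as zero; profiles are reported on a finite grid with no
claim outside it.

## Physics tables

Bundled as CSV package data (one file per material, `materials.json`
manifest), 30 keV–3 MeV on a logarithmic grid with anchor knots at the
energies used throughout (50, 140.5, 350, 400, 511 keV, …); log-log
linear interpolation, exact at knots.  Materials: water, air, perpex
(PMMA), NaI, BGO (Bi₄Ge₃O₁₂), GSO (Gd₂SiO₅), CdWO₄, lead, tungsten, tin.

Construction (`tools/generate_attenuation_tables.py`):

* **Incoherent channel** — exact total Klein–Nishina cross section on
  free electrons × electron density N_A(Z/A). Binding corrections are
  neglected (<2% above 50 keV for these materials, a few % at 30 keV).
* **Photoelectric channel** — per-element amplitude at 511 keV times a
  shared piecewise log-log power-law shape (exponent 2.6 below 300 keV
  flattening to 1.6 by 3 MeV, fitted to lead; a steeper variant for
  Z ≤ 14). Amplitudes are anchored to standard detector-physics data:
  lead from NIST grid values; Bi, Gd and I from the 511 keV attenuation
  lengths of BGO (1.05 cm), GSO (1.38 cm) and NaI (2.88 cm) with their
  photo-fractions (≈0.43/0.26/0.18). K-edges inside the grid (I, Gd, W,
  Pb, Bi) are modelled as a division by the literature jump ratio below
  the edge, with straddling grid knots.
* **"Total" = photoelectric + incoherent.** Coherent (Rayleigh)
  scattering is excluded throughout — the narrow-beam convention under
  which water μ(E) is strictly decreasing over the full grid, which the
  bijective μ↔E mapping requires; pair production is out of scope.
  Consequently high-Z totals above ~1.2 MeV sit a few percent below
  literature values.

Accuracy matters mostly through (i) the water μ(E) curve, which is
reproduced to ≈1% against narrow-beam reference values across 50–350
keV, and (ii) the scintillator cross sections at 150–600 keV, where the
anchoring is at the few-percent level.  Element-level shape errors of
~10–20% below 150 keV are tolerated deliberately: photons there are
almost surely photo-absorbed in any of these crystals, so full-energy
results are insensitive to them.

The bremsstrahlung yield a(E) is a bundled relative spectrum built by
folding the Kramers thin-target intensity ((T−E)/E) over an
allowed-shape ⁹⁰Y beta spectrum with 2300 keV endpoint, normalized to
unit integral and zero at and above the endpoint.  Its absolute scale
and fine shape are irrelevant by construction — a(E) cancels in C —
only positivity and support matter; the table is user-replaceable.

## Forward projector

Siddon-style exact voxel traversal: parametric crossings of all lattice
planes give per-voxel chords; no sampling.  Attenuation is the exact
per-material line integral over traversed media, evaluated at each
chord midpoint (air advances depth but does not attenuate, matching the
model's l − l_p convention; for a homogeneous water phantom the
projector reduces to the model identically).  For pinhole rays, chords
are subdivided to ≤0.1 of the local source–aperture distance before the
midpoint rule is applied — G ∝ 1/h² curves too fast near the aperture
for single-midpoint quadrature (without subdivision the error reaches
~10% at h ≈ 1 cm; with it, <0.1% everywhere, verified against a 10 μm
brute-force integrator).  The projector is linear in the activity grid
to rounding.

Pixel centers sit at (i + 0.5)·pitch − extent/2 on a 45 × 25 cm
detector at 5 mm pitch by default; energy bins default to 2 keV over
the extended (50, 350) keV acquisition window.

Detector response (optional, off for the ideal-camera analyses): scale
by intrinsic full-energy efficiency ε(E) (the analytic 1 − e^{−μt} of
the camera crystal, or any callable), convolve with a Gaussian of
FWHM(E) = r·√(E·E_ref) (default r chosen so FWHM = 20% at 511 keV,
BGO-block-like), then zero bins outside the window.  The blur matrix is
built from Gaussian CDFs with the outer bins absorbing the tails, so it
conserves counts exactly before windowing.

## Inverse Laplace reconstruction

Discretization: depth grid 0–30 cm at 0.5 cm (liver scale); kernel
K[i,j] = w_j e^{−μ_i l_j} with trapezoid weights.  The inversion solves

    min ‖K Ā − Ĉ‖² + λ ‖D Ā‖²   s.t.  Ā ≥ 0 (optional),

with D the difference operator of order 0–2 (default 2), by
non-negative least squares on the √λ-stacked system.  λ is either fixed
or chosen by Morozov's discrepancy principle (bisection on log λ; the
residual is monotone in λ).  Two honest failure modes are surfaced in
the diagnostics rather than hidden: (i) the kernel condition number
grows geometrically with the number of depth nodes and exceeds 1/ε of
double precision already at ~20 nodes for the clinical μ window, so the
zero-λ residual has a numerical floor; (ii) under the non-negativity
constraint a noise realization may lie outside the cone of attainable
data, making the discrepancy target unreachable — the result is then
flagged `converged: False` with the floor residual reported.

**Depth resolution is bounded by the μ dynamic range.**  Within the
(50, 350) keV window, water μ spans only [0.112, 0.219] cm⁻¹ — a factor
two.  A point source is localized sharply (noiseless forward-then-invert
recovers the center of mass within one 0.5 cm cell, and the log-linear
closed-form estimator −d ln Ĉ/dμ is exact), but an equal-mass doublet at
5 and 15 cm is mimicked by a single exponential to 0.5% relative — below
any realistic noise floor — and is therefore *unresolvable in principle*
in that window; the test suite asserts this bound explicitly.  With the
full bijective span (30 keV–2.2 MeV) and 10⁻⁴ relative noise the same
doublet is recovered to the grid cell.  This is the quantitative face of
the known severe ill-posedness of real-axis Laplace inversion, and the
reason the energy coordinate complements rather than replaces angular
sampling.

Tie-breaks: NNLS may return different supports for symmetric data; all
assertions are on residuals and centers of mass, never exact support.

## Crystal Monte Carlo

Pencil beam at normal incidence on an infinite transverse slab.
Histories alternate exponential free flights (total μ) with
interactions branched photoelectric vs Compton by cross-section ratio;
Compton samples the Klein–Nishina density in x = E′/E by rejection
under the envelope x + 1/x ≤ 1/x_min + 1, deposits the recoil locally,
and rotates the direction cosine.  Electrons are locally absorbed (no
electron transport, secondary bremsstrahlung, or K-fluorescence
escape); a photon below the 30 keV table floor is locally absorbed (its
photoelectric mean free path in these crystals is sub-millimetre).
"Full energy" means cumulative deposit = incident energy to 1e-9
relative.  Tallies partition the histories exactly; binomial standard
errors are reported; a seed is a required argument of every stochastic
entry point and fixes the result bit-for-bit.

The photoelectric-only channel mode reproduces 1 − e^{−μ_pe t}
analytically and serves as the transport self-check; the Klein–Nishina
sampler is checked against direct quadrature of the differential cross
section.

Known biases: ignoring K-escape inflates thin-NaI full-energy fractions
by ~1–2 pp (the relevant tolerance is widened accordingly); excluding
coherent scattering deflates capture marginally.  The measured 30 mm
full-energy fractions at 511 keV (BGO ≈ 89%, GSO ≈ 77%, NaI 3/8″ ≈ 12%)
sit a few pp below the corresponding total-attenuation numbers
(94%/89%/27%), the gap growing as the photo-fraction falls — GSO's
published ≈84% figure is consistent with an attenuation-derived curve
but not reachable by a full-energy MC under literature-anchored GSO
cross sections (it would need Gd photoelectric ≈35% above the value
implied by the 1.38 cm attenuation length).

## Calibration

Gain model: factor = 1 + c·(T − T₀) with c = −0.012/K (BGO light
yield); domain-checked to stay positive.  Reference-peak fitting:
Gaussian centroid by least squares inside a user window seeded at the
discrete argmax; rescaling multiplies every event energy by
nominal/measured peak — linear through zero, matching the
multiplicative drift mechanism (no offset term; an electronics pedestal
would need one).  The ⁹⁹ᵐTc photopeak constant 140.5 keV is a nuclide
datum, configurable.  The round trip (distort by ±10 K, fit, rescale)
restores the peak to <0.2%.

## Synthetic data

The generators define the study conditions; they are first-class,
tested code.

* `point_source_phantom` — the bench validation object: one hot voxel
  (default 1 Bq-equivalent, conserved exactly) at a fixed 20 cm detector
  distance under a chosen water cover, inside a 1 cm perpex shell;
  0.5 cm voxels, 10 cm transverse field.  The surface snaps to a voxel
  boundary; the realized geometry is recorded in `phantom.meta`.
* `liver_phantom` — primitive-based rasterizer (ellipsoid/sphere/box,
  last-wins overlap), activity anti-aliased by 2³ sub-voxel sampling so
  a 2 cm sphere's activity is conserved to ≈0.3% at 2 mm voxels.
* `generate_acquisition` — Poisson counts with mean = live time ×
  detector-response(projection), seed-reproducible, with a provenance
  hash.

Default camera: 45 × 25 cm field at 5 mm pixels; pinhole with 8 mm
aperture and F = 15 cm; extended (50, 350) keV window; *ideal* energy
response (r = 0, ε ≡ 1) — the assumption under which the Laplace
identity is exact, and the regime all depth-recovery results refer to.
What the synthetic tests therefore do **not** show: behavior under
patient/collimator scatter, septal penetration, lead fluorescence,
back-compartment backscatter, finite energy resolution, or dead time.
Those contaminations dominate real bremsstrahlung acquisitions and are
outside this package's scope.

## Problem sizes and determinism

Monte Carlo targets use 10⁵ histories at 511 keV and 10⁶ at 400 keV
(standard errors ≈0.1 pp and ≈0.04 pp); the end-to-end depth property
uses 200 Poisson replicates of a 10⁵-count acquisition; doublet
recovery uses 100 noise seeds.  These sizes put the statistical error
well under the assertion tolerances.  Every stochastic test fixes its
seed; hypothesis-based property tests run derandomized.

## Known limitations

* Cross sections are constructed, not fetched from a reference
  database; their anchoring accuracy (few %) is the dominant systematic
  of the crystal MC.
* The pinhole efficiency formula (d²·sin³θ/16h²) ignores aperture edge
  penetration and the collimator housing; parallel-hole G uses the
  standard hexagonal-packing constant 0.26 with no septal penetration.
* The projector treats activity per voxel as a line density sampled on
  the chord (exact for the single-voxel and analytic comparisons used
  here; a volume-integral projector would differ for coarse voxels at
  strong magnification).
* Rescaling calibration assumes a single gain factor per block; no
  per-energy nonlinearity.
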