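# bremstomo

Energy-resolved bremsstrahlung imaging for ⁹⁰Y liver radioembolization:
a forward model in which the recorded x-ray energy encodes source depth,
its reduction to a Laplace transform and regularized numerical
inversion, a scintillator-slab photon-transport Monte Carlo for crystal
selection, and the temperature gain calibration of a BGO prototype
camera.

## The problem

⁹⁰Y microspheres injected into the hepatic artery treat liver tumors by
local beta irradiation.  Verifying the delivered dose in the
catheterization room needs a fast quantitative image, but ⁹⁰Y emits no
gamma line — only continuous bremsstrahlung up to the 2.3 MeV beta
endpoint, which conventional Anger cameras image poorly (<15% of
recorded events are geometric).  A camera built around a thick
high-Z crystal (30 mm BGO) and a heavily shielded pinhole collimator
can use an extended 50–350 keV acquisition window, and then the event
energy itself carries tomographic information.

For an ideal camera above a water-equivalent patient, the count-rate
density in pixel (x, y) is

```
c(x,y,E) = ∫ a(E) A(r(l)) G(r(l)) exp(−μ(E)(l − l_p(x,y))) dl
```

with A the activity, G the collimator geometric efficiency, a(E) the
bremsstrahlung yield in water, μ(E) the water attenuation coefficient
and l_p the patient-surface intercept of the line of response r(l).
Because μ(E) is bijective for water, the normalized spectrum
`C = c·exp(−μ(E)l_p)/a(E)`, re-parameterized from E to μ, is the
**Laplace transform in depth** of the effective profile Ā(l) = A·G —
energy plays the role of the rotation angle in conventional SPECT.  The
package implements this projector exactly (Siddon ray traversal,
per-material attenuation), inverts it by penalized non-negative least
squares with discrepancy-based regularization, and quantifies the
depth-resolution bound imposed by the factor-two μ dynamic range of the
clinical window.

The supporting hardware questions are modelled at desk scale: a
photoelectric + Klein–Nishina Monte Carlo computes full-energy
absorption efficiencies of candidate crystals (NaI, GSO, BGO, CdWO₄),
and the calibration module implements the −1.2%/K BGO gain drift and
its ⁹⁹ᵐTc reference-peak rescaling correction.

## Worked example

```
$ python examples/01_depth_from_energy_spectrum.py
patient surface at lp = 10.25 cm from the detector
true source position along the LOR: 20.00 cm
log-linear estimate:   20.10 cm
inversion center of mass: 20.44 cm (lambda = 1.0e-06, residual = 1.42e-08)
```

A point source 10 cm under water is projected through an ideal
parallel-hole camera; normalizing the 50–350 keV spectrum and relabeling
energy by water μ gives Ĉ(μ) ≈ const·e^{−lμ}, so the slope of ln Ĉ
reads off the source position l (20 cm from the detector) to within a
millimetre or two — the perpex shell around the source accounts for the
small offset through its water-equivalent thickness.

```
$ python examples/02_crystal_efficiency.py
full-energy efficiency at 511 keV (1e5 histories):
  NaI 3/8"      11.8 % (+/- 0.1)
  GSO 30 mm     77.1 % (+/- 0.1)
  BGO 30 mm     89.0 % (+/- 0.1)
  CdWO4 30 mm   84.6 % (+/- 0.1)

BGO(30 mm) / NaI(9.525 mm) at 400 keV: 5.40
```

The thick BGO slab converts ~9 in 10 photons at 511 keV into
full-energy events versus ~1 in 8 for the 3/8″ NaI of a conventional
camera — the case for a dedicated detector.  `examples/03` covers the
pinhole geometry (aperture intersection, unit magnification at 2F,
inverse-square sensitivity, the ~64 kg lead front wall) and
`examples/04` the gain-drift round trip.

## Command line

A thin CLI wraps the library:

```
bremstomo phantom   --spec spec.json --out liver
bremstomo acquire   --phantom liver --live-time 60 --seed 1 --out spectra.csv
bremstomo normalize --spectra spectra.csv --phantom liver --pixel 2275 --out mu.csv
bremstomo recon     --mu mu.csv --lam 1e-6 --out profile.csv
bremstomo crystal-eff --material BGO --thickness-mm 30 --energy-kev 511 \
                      --n 100000 --seed 1 --out eff.csv
bremstomo calibrate --events events.csv --reference ref.csv --out corrected.csv
```

Every artifact gets a `.meta.json` sidecar with the config hash, seed
and package version.

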