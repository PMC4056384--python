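"""Depth of a buried Y-90 point source from its bremsstrahlung spectrum.

Builds the bench validation object (a point source under 10 cm of water
with a 1 cm perpex shell), projects it through an ideal parallel-hole
camera over the extended 50-350 keV window, normalizes the spectrum,
re-parameterizes energy to the water attenuation coefficient, and reads
the source position two ways: the closed-form log-linear estimator and
the regularized inverse Laplace transform.
"""

import numpy as np

from bremstomo import (InversionConfig, MuSpectrum, default_camera,
                       invert_laplace, normalize, parallel_lor,
                       point_source_depth, point_source_phantom, project,
                       rebin_to_mu, surface_depth)

phantom = point_source_phantom(depth=10.0)
camera = default_camera("parallel")
lor = parallel_lor(0.0, 0.0)

lp = surface_depth(phantom, lor)
spectrum = project(phantom, camera, pixels=[(0.0, 0.0)])
mu_spec = rebin_to_mu(normalize(spectrum, lp))[0]

d_closed = point_source_depth(mu_spec)
profile = invert_laplace(mu_spec, InversionConfig(lam=1e-6))

print(f"patient surface at lp = {lp:.2f} cm from the detector")
print(f"true source position along the LOR: "
      f"{phantom.meta['source_center_z']:.2f} cm")
print(f"log-linear estimate:   {d_closed:.2f} cm")
print(f"inversion center of mass: {profile.center_of_mass():.2f} cm "
      f"(lambda = {profile.diagnostics['lam']:.1e}, "
      f"residual = {profile.diagnostics['residual']:.2e})")
print()
print("The recorded energy encodes depth through the water attenuation")
print("mu(E): both estimates should sit within a few mm of the true")
print("source position (the log-linear one is exact for a point source;")
print("the perpex shell shifts it slightly via its water-equivalent")
print("thickness).")
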