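"""Bend/swivel orientation of the epsilon-site-bearing helix segment.

Measures the bend angle theta and swivel angle Phi of the I47-M51 segment
relative to A30-L34 (G33 Calpha defines the zero azimuth), and bins the
orientations the way polar-histogram summaries of cleavage-domain
presentation are built.
"""
import numpy as np

from tmdyn import (ALPHA, HingeSpec, bend_swivel, build_ideal_helix,
                   generate_hinge_ensemble, orientation_statistics,
                   residue_azimuth)
from tmdyn.constants import C99_WT_CONSTRUCT

base = build_ideal_helix(C99_WT_CONSTRUCT, ALPHA)
print("azimuth ladder of the built ideal helix (deg):")
for r in (29, 33, 37, 38):
    print(f"  G-ladder residue {r}: {residue_azimuth(base, residue=r):7.1f}")

spec = HingeSpec(hinge=37, bend_mean=25.0, bend_sd=12.0,
                 azimuth_mean=-40.0, azimuth_sd=30.0)
ens = generate_hinge_ensemble(base, spec, 2000, seed=2)
series = bend_swivel(ens)
stats = orientation_statistics(series)

print(f"\nmean bend theta = {np.nanmean(series.theta):.1f} deg, "
      f"median swivel Phi = {np.nanmedian(series.phi):.1f} deg")
print("bend classes  small/intermediate/large:",
      np.round(stats.theta_class_populations, 3))
print("swivel 45-deg bin populations:",
      np.round(stats.phi_populations, 3))
print("\nThe swivel distribution peaks near Phi = -40 deg: the helix bends")
print("preferentially toward the di-glycine (G37) interface.")
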