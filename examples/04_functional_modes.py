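"""PLS functional mode analysis against an H-bond order parameter.

Finds the collective backbone motion most correlated with the count of
closed H-bonds in the central (region I) carbonyl set of a hinge-bending
ensemble, cross-validates it on held-out frames and locates the hinge in
the low/high-occupancy endpoint structures.
"""
import numpy as np

from tmdyn import (ALPHA, HingeSpec, build_ideal_helix, ewmcm_interpolation,
                   fit_fma, generate_hinge_ensemble, order_parameter,
                   screw_decomposition, select_components)
from tmdyn.constants import C99_WT_CONSTRUCT

base = build_ideal_helix(C99_WT_CONSTRUCT, ALPHA)
spec = HingeSpec(hinge=37, bend_mean=22.0, bend_sd=14.0, azimuth_mean=-40.0,
                 noise_sd=0.05)
ens = generate_hinge_ensemble(base, spec, 1200, seed=5)

y = order_parameter(ens, "region1")
print(f"order parameter: closed H-bonds over carbonyls G33-G38, "
      f"range {y.values.min():.0f}-{y.values.max():.0f} of {y.n_bonds}")

sel = select_components(ens, y, max_components=8)
print("R_m curve:", np.round(sel.r_m_curve, 3), "-> chose",
      sel.n_components, "components")

fm = fit_fma(ens, y, n_components=sel.n_components or 3)
print(f"training R_m = {fm.r_m:.3f}, cross-validation R_c = {fm.r_c:.3f}")

path = ewmcm_interpolation(fm, ens, n_steps=2)
dec = screw_decomposition(path.frame(1), path.frame(0))
print(f"hinge in the ewMCM endpoints: residues {dec.hinges[0]}, "
      f"type {dec.motion_type}")
print("\nA high R_c on unseen frames means the mode is predictive, not a")
print("fit artefact; the endpoint decomposition recovers the G37 hinge that")
print("generated the occupancy fluctuations.")
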