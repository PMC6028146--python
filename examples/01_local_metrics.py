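"""Local backbone metrics of a bending transmembrane helix.

Builds the ideal alpha-helical C99(28-55) construct, samples a hinge-bending
ensemble at the di-glycine hinge G37, and prints H-bond occupancies, packing
scores and rise per residue for the helical core.
"""
import numpy as np

from tmdyn import (ALPHA, HingeSpec, build_ideal_helix, generate_hinge_ensemble,
                   hbond_occupancy, packing_score, rise_per_residue)
from tmdyn.constants import C99_WT_CONSTRUCT

base = build_ideal_helix(C99_WT_CONSTRUCT, ALPHA)
spec = HingeSpec(hinge=37, bend_mean=25.0, bend_sd=12.0, azimuth_sd=25.0,
                 noise_sd=0.15)
ens = generate_hinge_ensemble(base, spec, 400, seed=1)

occ = hbond_occupancy(ens)
pack = packing_score(ens)
rise = rise_per_residue(ens)

print("res   occ(a|3_10)  packing(x100)  rise/A")
for n in range(30, 52):
    i = ens.residue_map.index_of(n)
    print(f"{ens.residue_map.label(n):>4}  {occ.combined[i]:11.2f}"
          f"  {pack.values[i]:13.2f}  {rise.values[i]:6.2f}")
print("\nOccupancy dips around the hinge (G33-G37 carbonyls) mark the")
print("H-bonds that stretch on the convex side of the bend; packing and")
print("rise stay near their ideal-helix values elsewhere (~1.5-1.6 A rise).")
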