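"""Quasi-harmonic perturbation-response scanning of implicit enzyme binding.

Starts from an exactly known harmonic model of a 15-residue helix, couples
the N-terminal glycine face to an implicit enzyme chain (binding model 5:
residues 29-38, gamma = 5, kappa = 150 kcal mol^-1 A^-2), and shows how
binding redistributes backbone fluctuations and reorganises the essential
mode space.
"""
import numpy as np

from tmdyn import (BindingModel, Conformation, CovarianceMatrix, HarmonicModel,
                   ResidueMap, anm_hessian, apply_binding, essential_subspace,
                   overlap, parametric_ca_helix, prs_scan)
from tmdyn.ensemble import Topology

n = 15
rm = ResidueMap.linear("G" * n, start=29)
ca = parametric_ca_helix("G" * n, residue_map=rm).ca()
model = HarmonicModel(Conformation(Topology.calpha(n), ca, rm),
                      anm_hessian(ca, cutoff=10.0, k=2.0))
C_u = CovarianceMatrix(model.analytic_covariance(), list(range(29, 29 + n)),
                       temperature=model.temperature)

res = apply_binding(C_u, BindingModel.preset("model5"))
print("res   MSF_pre  MSF_bound   Z_diff  significant")
for i, r in enumerate(C_u.residues):
    star = "*" if res.significant[i] else ""
    print(f"{r:4d}  {res.msf_unbound[i]:7.2f}  {res.msf_bound[i]:9.2f}"
          f"  {res.z_diff[i]:7.2f}  {star}")

sub_u = essential_subspace(C_u, 0.85)
sub_b = essential_subspace(res.covariance_bound, 0.85)
print(f"\nessential modes covering 85% MSF: pre-bound n={sub_u.n_modes}, "
      f"bound n={sub_b.n_modes}")
half_b = essential_subspace(res.covariance_bound, 0.5)
v1 = sub_u.vectors[:, 0]
cum_half, _ = overlap(v1, half_b)
print(f"overlap of the dominant pre-bound mode with the leading bound modes "
      f"(50% MSF, n={half_b.n_modes}): {cum_half:.2f}")

Z, sites, cols = prs_scan(C_u)
k = sites.index(33)
print(f"\nsingle-site scan, binding at G33: strongest distal response at "
      f"residue {cols[int(np.nanargmax(np.abs(Z[k])))]} "
      f"(Z = {np.nanmax(np.abs(Z[k])):.2f})")
print("\nBinding stiffens the contacted N-terminal face (negative MSF")
print("change there) while fluctuations redistribute toward the free")
print("C-terminal half - the communication that positions the cleavage sites.")
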