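# Methods

This note records the models behind each analysis, the defaults and why,
the numerical choices, and what the synthetic generators do and do not
emulate.

## System and coordinates

The reference system is the transmembrane domain of the amyloid precursor
protein C99 fragment: a model peptide of C99 residues 28–55 with an
N-terminal KKW tag (wild type KKWK-GAIIGLMVGGVVIATVIVITLVML-KKK). C99
numbering is the public residue coordinate everywhere; 0-based construct
indices exist only inside the topology. Coordinates are Å, energies
kcal/mol, spring constants kcal mol⁻¹ Å⁻², times ns, angles degrees.
k_B = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹; the default temperature is 293 K
(k_BT = 0.5822 kcal/mol).

## Ensembles, superposition, mean structures

Superposition is Kabsch least squares (SVD with reflection correction) on a
selection, by default the Cα atoms; the fit rejects near-collinear point
sets. The mean structure is the fixed point of (superpose → average),
initialised from the first frame rather than the plain coordinate average —
averaging unaligned frames can produce a degenerate (near-collinear) point
set, e.g. for two frames related by a 180° rotation. Convergence is declared
when the mean moves by less than `tol` (default 10⁻⁶ Å RMSD); the iterate
and a flag are returned on non-convergence. The result is invariant under
frame permutation up to a global rigid motion, which is how the property
test compares it.

Missing backbone amide hydrogens (XTC inputs, Cα-only builders) are
reconstructed geometrically: H at 1.01 Å from N, in the C(i−1)–N–Cα plane,
opposite the bisector of those two bonds. On the internal-coordinate helix
builder this reproduces the built hydrogens to 10⁻⁹ Å because the builder
uses the same placement rule.

## H-bonds, occupancies and the order parameters

A backbone H-bond is closed when the H···O distance is ≤ 2.6 Å **and** the
N–H···O angle is within 180°±60°; ties at the distance boundary count as
closed. Occupancy is assigned to the carbonyl (acceptor) residue i, with an
α (i→i+4) and a 3₁₀ (i→i+3) channel; the combined occupancy is the fraction
of frames with either channel closed, hence bounded below by each channel
and above by their sum. Carbonyls without a partner (chain end, missing
amide H) are flagged undefined, never zero-filled. The FMA order parameters
are integer counts of closed combined bonds over the carbonyl sets G33–G38
(region I) and V40–T43 (region II).

## Packing score, hydration, dihedrals, rise

The packing score of residue i is S(i) = Σⱼ r(i,j)⁻⁶ over all peptide atoms
j outside residue i, measured from the carbonyl O of i and reported ×100.
All non-self atoms enter the sum, hydrogens of other residues included —
this is the literal reading of a cut-off-free all-atom contact measure.
Frames containing an atom pair closer than 0.5 Å are rejected with the frame
indices recorded. Water coordination counts water hydrogens within 2.6 Å of
the carbonyl O (the same cut-off as the H-bond criterion); a per-molecule
cap is available because whether two hydrogens of one water count once or
twice is a convention, not a fact. Backbone dihedrals are summarised with
circular statistics (vector mean, circular SD) — linear averaging is wrong
near ±180°.

Rise per residue is differential-geometric: with bisectors
b(i) = unit[(Cα(i−1)−Cα(i)) + (Cα(i+1)−Cα(i))], the local axis is
unit[b(i)×b(i+1)] and the rise is |(Cα(i+1)−Cα(i))·axis|. It is exact on a
parametric helix, undefined at the two terminal pairs, and NaN-flagged on
collinear degenerate geometry. Arc lengths are sums of local rises and are
exactly additive. On the straight-helix convention (rise exactly 1.5 Å) the
distances G33→V50 and G33→L49 are 25.5 and 24.0 Å, and the G38→ε-site
lengths are 7.5 Å shorter.

The dihedral presets are the textbook values α (φ=−57°, ψ=−47°) and 3₁₀
(φ=−49°, ψ=−26°) with standard bond geometry (N–Cα 1.458, Cα–C 1.525,
C–N 1.329 Å). The resulting differential-geometric rises are 1.56 Å (α) and
1.99 Å (3₁₀) — within 0.04 Å of the conventional 1.52/1.96 Å reference
values, the level of agreement one expects between independent "ideal helix"
conventions; the package's tests assert the references at ±0.05 Å.

## Orientation frame, bend and swivel

Segment axes are fitted differential-geometrically: the mean of successive
bisector cross products gives the direction (sign fixed N→C), and a
least-squares circle fit in the normal plane gives the anchor point. This
fit is exact on an ideal helix for windows as short as 4–5 residues. A
principal-component fit was rejected after measurement: on a 5-residue
window of an ideal helix the raw-Cα principal axis is tilted ~10° from the
true helix axis (five points cover 1.4 turns — the in-plane anisotropy
competes with the rise), which is fatal for azimuth work.

The orientation frame puts the TM-N segment (A30–L34) axis on +z (N→C) and
rotates about z until the G33 Cα projects onto +x. Azimuths are measured
clockwise viewed from the C-terminal (+z) end (y = x×z in the atan2). This
sign convention is pinned by the glycine ladder: on an exact
3.6-residue/turn right-handed helix G29/G33/G37/G38 sit at +40/0/−40/−140°.
(A counter-clockwise frame would flip every sign.) The dihedral-built α
preset winds 99.35°/residue (3.63 res/turn), so its ladder lands at
+37.4/0/−37.4/−136.8° — a few degrees from the exact-3.6 arithmetic, which
is why the reference azimuths are computed on the parametric helix.

The bend angle θ is the angle between the TM-C (I47–M51) segment axis and
+z; the swivel Φ is the azimuth of that axis' projection. Φ is reported
undefined (NaN) when θ < 2° — the azimuth of a near-parallel axis is noise.
Orientation statistics use 45° swivel bins centred on 0°, left-closed bend
classes [0,20), [20,40), [40,∞), and a 2°×2° polar histogram normalised to
its highest bin.

## Hinge decomposition (screw-axis surrogate)

The decomposition is a transparent stand-in for dynamic-domain programs
whose internal clustering is not re-derivable from their publications, and
it is validated against constructed motions only. For each 5-residue
sliding window a Kabsch rotation onto the reference (the frame with the
lowest RMSD from the mean structure) is computed. Windows are agglomerated
along the sequence: a window joins the running cluster while its rotation is
within `cluster_angle_tol` (default 15°) of the cluster's mean rotation —
comparing with the cluster mean rather than the previous window prevents
transitive chaining across a hinge. Residues covered only by windows of one
cluster form quasi-rigid domains (≥4 residues); residues whose windows
disagree are the hinge set. Each domain's rotation is averaged over windows
fully inside it (straddling windows would dilute the angle; with them
excluded a constructed noiseless 30° bend is recovered at 30.00°). For each
adjacent domain pair the relative rotation gives the screw axis;
%closure = 100·sin²∠(screw axis, reference helix axis), bending for >50,
twisting otherwise. Motion types: none (no inter-domain rotation ≥5°), B/T
(one hinge), the four two-hinge combinations ordered N→C, M (more). The
double-hinge angle estimate is less sharp than the single-hinge one because
a 4-residue middle domain contains no fully interior window.

## PLS functional mode analysis

Predictors are the centred coordinates of the heavy backbone atoms (N, Cα,
C, O) of the mapped range (K28–K54 where present) after superposition onto
the iterative mean. The train/validation split is chronological (first half
trains) — a random split would leak autocorrelated frames across the
boundary. The PLS regression (scikit-learn, no scaling) gives a coefficient
vector β; the reported mode is the **ensemble-weighted** maximally
correlated motion ewMCM ∝ C·β (training covariance applied to the
regression direction), unit-normalised, signed so that increasing projection
increases the order parameter. The weighting matters: β is the direction
that predicts the order parameter, C·β is the collective *motion* actually
present in the ensemble that carries that prediction. R_m and R_c are
Pearson correlations between model and data on the training and held-out
halves. The default component count is 13; `select_components` returns the
smallest count whose R_m exceeds 0.75 with increments below 0.01.
Interpolation structures run from the 1st to the 99th percentile of the
training projections; `n_steps=1` returns the mean structure. Mode
similarity is the |inner product| matrix with complete-linkage clustering on
1−|dot|.

Validation is by planted-model recovery: ensembles whose dominant motion is
a known mode and whose order parameter is that mode's amplitude plus noise
(SNR 10). Over 20 seeds the median |⟨ewMCM, planted⟩| and median R_c exceed
0.9; a permuted order parameter gives |R_c| < 0.15. This tests the
estimator, not any particular biological mode.

## Perturbation-response scanning

The pre-bound peptide is quasi-harmonic: H_u = k_BT·C_u⁺ over the Cα atoms
of the helical core. The enzyme is a linear chain of M implicit sites;
couplings enter a combined Hessian as −γE₃ off-diagonal blocks with
diagonal closure (every row/column of the interacting system sums to zero),
and the chain carries −κE₃ nearest-neighbour blocks. Eliminating the enzyme
block by Schur complement yields the stiffness increment
δH = D − H_SE·H_EE⁻¹·H_ES, which is positive semidefinite — binding can
only remove fluctuation, never add it (trace(C_b) ≤ trace(C_u), and every
directly bound residue's MSF decreases).

The bound covariance is computed by the resolvent route
C_b = (I + C_u·δH/k_BT)⁻¹·C_u, which needs no pseudo-inversion and confines
the response to the sampled fluctuation space (the range of C_u). For a
full-rank covariance this is algebraically identical to inverting
H_u + δH, and it equals the substrate block of the inverted full
substrate+enzyme Hessian to machine precision — the package's primary
correctness test, run for all five preset models and generic small systems.
For rank-deficient quasi-harmonic covariances the resolvent route is the
physically correct choice: modes with zero sampled fluctuation stay
unexcitable, whereas pseudo-inverting the effective Hessian would let the
binding springs inject fluctuation into unsampled rigid-body remnants.

A free enzyme fragment attached to the peptide at a *single* point
eliminates to δH = 0 exactly (the fragment simply follows), so meaningful
single-residue perturbations hold the enzyme site fixed: the scan uses
grounded springs, δH = γE₃ at the bound residue. Multi-site preset models
use the free-chain elimination, which produces pure relative-displacement
couplings between the bound residues (translation-invariant by
construction). With γ = 0 the increment is identically zero.

γ defaults to 5 and κ to 150 kcal mol⁻¹ Å⁻²; `calibrate_gamma` reports
ΔMSF(i) = (MSF_b−MSF_u)/MSF_u² against γ and flags the linear-response
regime (slope drift < 10%). Spectral pseudo-inversions drop the 6 smallest
modes of ensemble-derived covariances (rigid-body remnants) plus anything
below 10⁻¹⁰ of the largest eigenvalue; analytic full-rank covariances use
`n_removed=0`.

Fluctuation changes are standardised per the two-step recipe: each MSF
profile is normalised by mean and SD over non-outlier residues (outliers by
modified Z-score — median/MAD with the 0.6745 scaling — above 3.5), the
profile difference is standardised the same way to give Z_diff, and |Z| > 1
marks significance. Flat profiles or flat differences make F_norm or Z_diff
undefined; both cases are flagged rather than zero-filled. Note that Z_diff
is a *relative* statistic: stiffening one residue shifts the normalisation
of every other, so off-site Z_diff entries are not zero even when off-site
MSFs are untouched — the scan's raw MSF matrix is exactly local for a
diagonal covariance.

The essential subspace is the smallest set of leading covariance
eigenvectors covering a target MSF fraction (default 85%). Mode overlap with
a subspace is reported both as the cumulative Σᵢ(FM·vᵢ)² ∈ [0,1] (the
primary statistic) and as the per-mode average (divided by n); functional
modes over backbone atoms are restricted to their Cα components and
renormalised before comparison.

## Synthetic generators: what they emulate and what they do not

The hinge sampler rotates the sub-chain C-terminal of a pivot Cα by sampled
bend/azimuth/twist angles and adds isotropic noise, storing the drawn angles
as frame metadata; its defaults (bend ~25–30°, sd ~12–15°, azimuth near the
−40° glycine face) mirror the intermediate-bending regime a TMD helix
samples. The harmonic sampler draws frames from N(mean, k_BT·H⁺) with zero
modes excluded, so its covariance is known exactly. Solvent clouds place
water (O+2H) and two-site TFE (centroid + hydroxyl) uniformly outside a 2 Å
exclusion shell.

None of these reproduce real MD: no anharmonic wells, no solvent dynamics
or dielectric screening, no side chains (packing tests therefore exercise
backbone atoms), no coupling between H-bond breaking and bending beyond the
geometric one. Passing tests therefore certify the *estimators* — that
occupancies, angles, modes and response matrices recover planted ground
truth — not any claim about the real peptide's dynamics, whose reference
values would require the original trajectories. All stochastic generators
take explicit seeds; there is no global RNG state.

## Problem sizes in the test-suite

Monte-Carlo checks use the smallest sizes at which their statistics are
sharp: 50 000 frames for the 5% covariance recovery of a 10-residue
harmonic helix, 10 000/40 000 frames (five seeds) for the n^{-1/2}
convergence of PRS predictions, 4 000 frames × 20 seeds for planted-mode
FMA recovery, 2 000 frames for bend-distribution recovery. Exact algebraic
identities (oracle equivalence, route equivalence, additivity, isometry)
are asserted at 10⁻⁸–10⁻¹² on 5–15-residue systems.

## Known limitations

- The hinge decomposition is a documented surrogate; its %closure is a
  geometric definition, not the ratio-based quantity of the established
  dynamic-domain programs, and the two have not been compared numerically.
- The ewMCM weighting follows the covariance-rescaling construction
  described above; it is validated by planted-mode recovery, not against
  the original PLS-FMA program.
- Binding springs are isotropic and distance-independent; no
  force-perturbation (linear-response kick) variant is provided.
- Solvent analyses assume whole (unwrapped) molecules; no periodic
  boundary handling.
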