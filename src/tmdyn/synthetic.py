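"""Synthetic ensembles with known ground truth.

Three generators make every downstream analysis stage testable without MD
data: an internal-coordinate (NeRF) ideal-helix builder, a hinge-bending
sampler producing frames with recorded bend/swivel/twist angles, and a
harmonic sampler drawing frames from a Gaussian whose exact covariance is
k_BT * H^+ for a user-supplied Hessian.  All stochastic operations take an
explicit seed; there is no hidden global RNG state.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import constants as K
from .ensemble import Conformation, Ensemble, Solvent, Topology, place_amide_hydrogen
from .geometry import DEFAULT_AZIMUTH_REF, TM_N, SegmentSpec, orientation_frame
from .residues import ONE_TO_THREE, ResidueMap


# --------------------------------------------------------------------------
# Ideal helix builders
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixParams:
    """Backbone dihedrals (deg) and the implied helix class."""

    phi: float
    psi: float
    omega: float = 180.0

    def __post_init__(self):
        if abs(((self.omega + 180.0) % 360.0) - 180.0) > 10.0 and \
           abs(abs(self.omega) - 180.0) > 10.0:
            raise ValueError("omega must be within 180 +/- 10 deg (trans)")


ALPHA = HelixParams(phi=-57.0, psi=-47.0)
THREE_TEN = HelixParams(phi=-49.0, psi=-26.0)


def _nerf(a, b, c, bond, angle, torsion):
    """Natural-extension-reference-frame placement of the next atom."""
    angle = np.deg2rad(angle)
    torsion = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.cos(torsion) * np.sin(angle),
                  bond * np.sin(torsion) * np.sin(angle)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_ideal_helix(sequence: str, params: HelixParams = ALPHA,
                      residue_map: ResidueMap | None = None) -> Conformation:
    """Backbone (N, H, CA, C, O) of an ideal helix from repeated dihedrals.

    Sequential internal-coordinate chain extension with standard bond
    lengths/angles.  Deterministic: identical inputs give bit-identical
    coordinates.
    """
    if len(sequence) < 5:
        raise ValueError("sequence too short for a helix (need >=5 residues)")
    for aa in sequence:
        if aa not in ONE_TO_THREE:
            raise ValueError(f"non-standard residue code {aa!r}")
    if residue_map is None:
        if sequence.startswith("KKW"):
            residue_map = ResidueMap.c99_construct(sequence)
        else:
            residue_map = ResidueMap.linear(sequence, start=1)

    n_res = len(sequence)
    N = [None] * n_res
    CA = [None] * n_res
    C = [None] * n_res
    N[0] = np.zeros(3)
    CA[0] = np.array([K.BOND_N_CA, 0.0, 0.0])
    C[0] = _nerf(np.array([0.0, -1.0, 0.0]), N[0], CA[0],
                 K.BOND_CA_C, K.ANGLE_N_CA_C, params.phi)
    for i in range(1, n_res):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1],
                     K.BOND_C_N, K.ANGLE_CA_C_N, params.psi)
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i],
                      K.BOND_N_CA, K.ANGLE_C_N_CA, params.omega)
        C[i] = _nerf(C[i - 1], N[i], CA[i],
                     K.BOND_CA_C, K.ANGLE_N_CA_C, params.phi)
    coords = []
    for i in range(n_res):
        coords.append(("N", i, N[i]))
        if i > 0 and sequence[i] != "P":
            coords.append(("H", i, place_amide_hydrogen(C[i - 1], N[i], CA[i])))
        coords.append(("CA", i, CA[i]))
        coords.append(("C", i, C[i]))
        # carbonyl O: anti to the next amide nitrogen (torsion psi+180)
        coords.append(("O", i, _nerf(N[i], CA[i], C[i],
                                     K.BOND_C_O, K.ANGLE_CA_C_O,
                                     params.psi + 180.0)))
    top = Topology(tuple(c[0] for c in coords),
                   np.array([c[1] for c in coords]),
                   tuple(c[0][0] for c in coords))
    xyz = np.array([c[2] for c in coords])
    return Conformation(top, xyz, residue_map)


def parametric_ca_helix(sequence: str, rise: float = K.IDEAL_RISE,
                        twist: float = K.IDEAL_TWIST_DEG,
                        radius: float = K.IDEAL_CA_RADIUS,
                        residue_map: ResidueMap | None = None) -> Conformation:
    """Exact mathematical right-handed Cα helix (default 3.6 res/turn, 1.5 A rise).

    The Cα-only idealisation used for straight-helix arc-length conventions
    and for the exact glycine azimuth ladder.
    """
    if residue_map is None:
        if sequence.startswith("KKW"):
            residue_map = ResidueMap.c99_construct(sequence)
        else:
            residue_map = ResidueMap.linear(sequence, start=1)
    t = np.arange(len(sequence), dtype=float)
    ang = np.deg2rad(twist * t)
    xyz = np.stack([radius * np.cos(ang), radius * np.sin(ang), rise * t], 1)
    return Conformation(Topology.calpha(len(sequence)), xyz, residue_map)


# --------------------------------------------------------------------------
# Hinge-bending sampler
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HingeSpec:
    """Stochastic hinge motion: bend/swivel/twist distributions (deg)."""

    hinge: int                         # C99 residue number of the pivot Cα
    bend_mean: float = 30.0
    bend_sd: float = 0.0
    azimuth_mean: float = -40.0        # bend direction in the S2-frame sense
    azimuth_sd: float = 0.0
    twist_mean: float = 0.0
    twist_sd: float = 0.0
    noise_sd: float = 0.0              # per-atom isotropic Gaussian noise (A)
    segment: SegmentSpec = TM_N        # frame-defining N-terminal segment
    azimuth_ref: int = DEFAULT_AZIMUTH_REF


def generate_hinge_ensemble(base: Conformation, spec: HingeSpec,
                            n_frames: int, seed: int,
                            frame_spacing_ns: float = 0.05) -> Ensemble:
    """Rotate the sub-chain C-terminal of the hinge by sampled bend/twist.

    Per frame: rotate all atoms of residues strictly C-terminal of the hinge
    about an axis through the hinge Cα (bend toward the sampled azimuth,
    plus a twist about the helix axis), then add isotropic noise.  Sampled
    ground-truth angles are stored in ``frame_meta``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    rmap = base.residue_map
    hinge_idx = rmap.index_of(spec.hinge)
    if hinge_idx == 0 or hinge_idx == rmap.n_residues - 1:
        raise ValueError("hinge at a terminal residue is not a hinge")
    x0, y0, z, _ = orientation_frame(base, spec.segment, spec.azimuth_ref)
    ica = base.topology.atom_index(hinge_idx, "CA")
    pivot = base.xyz[ica]
    mobile = base.topology.atom_resid > hinge_idx

    from scipy.spatial.transform import Rotation
    thetas = rng.normal(spec.bend_mean, spec.bend_sd, n_frames)
    azims = rng.normal(spec.azimuth_mean, spec.azimuth_sd, n_frames)
    twists = rng.normal(spec.twist_mean, spec.twist_sd, n_frames)
    xyz = np.repeat(base.xyz[None], n_frames, axis=0)
    for f in range(n_frames):
        th, az, tw = thetas[f], azims[f], twists[f]
        d = np.cos(np.deg2rad(az)) * x0 + np.sin(np.deg2rad(az)) * y0
        u = np.cross(z, d)
        u /= np.linalg.norm(u)
        R = (Rotation.from_rotvec(np.deg2rad(th) * u)
             * Rotation.from_rotvec(np.deg2rad(tw) * z)).as_matrix()
        xyz[f, mobile] = (xyz[f, mobile] - pivot) @ R.T + pivot
    if spec.noise_sd > 0:
        xyz += rng.normal(0.0, spec.noise_sd, xyz.shape)
    meta = {"theta": thetas, "phi": azims, "twist": twists,
            "hinge": spec.hinge, "seed": seed}
    return Ensemble(base.topology, xyz, rmap, frame_spacing_ns, frame_meta=meta)


# --------------------------------------------------------------------------
# Harmonic (quasi-Gaussian) sampler
# --------------------------------------------------------------------------

@dataclass
class HarmonicModel:
    """Mean structure plus a Hessian (kcal mol^-1 A^-2) over its atoms."""

    mean: Conformation
    hessian: np.ndarray
    temperature: float = K.DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        self.hessian = np.asarray(self.hessian, float)
        n = 3 * self.mean.topology.n_atoms
        if self.hessian.shape != (n, n):
            raise ValueError("Hessian dimension does not match mean structure")
        if not np.allclose(self.hessian, self.hessian.T, atol=1e-8):
            raise ValueError("Hessian must be symmetric")

    def analytic_covariance(self, rel_tol: float = 1e-10) -> np.ndarray:
        """k_BT * pseudo-inverse of the Hessian (zero modes excluded)."""
        w, v = np.linalg.eigh(self.hessian)
        keep = w > rel_tol * w.max()
        return K.kbt(self.temperature) * (v[:, keep] / w[keep]) @ v[:, keep].T


def generate_harmonic_ensemble(model: HarmonicModel, n_frames: int,
                               seed: int,
                               frame_spacing_ns: float = 0.05,
                               rel_tol: float = 1e-10) -> Ensemble:
    """Frames drawn from N(mean, k_BT * H^+), zero modes excluded."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    w, v = np.linalg.eigh(model.hessian)
    if w.min() < -rel_tol * max(w.max(), 1.0):
        raise ValueError(f"Hessian has negative eigenvalue {w.min():g}")
    keep = w > rel_tol * w.max()
    kbt = K.kbt(model.temperature)
    rng = np.random.default_rng(seed)
    q = rng.standard_normal((n_frames, int(keep.sum())))
    q *= np.sqrt(kbt / w[keep])
    disp = q @ v[:, keep].T
    xyz = model.mean.xyz[None] + disp.reshape(n_frames, -1, 3)
    meta = {"seed": seed, "n_modes": int(keep.sum()),
            "rank_deficient": n_frames - 1 < int(keep.sum())}
    return Ensemble(model.mean.topology, xyz, model.mean.residue_map,
                    frame_spacing_ns, frame_meta=meta)


def anm_hessian(ca: np.ndarray, cutoff: float = 10.0, k: float = 1.0) -> np.ndarray:
    """Anisotropic-network Hessian over Cα coordinates (6 zero modes)."""
    ca = np.asarray(ca, float)
    n = len(ca)
    H = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            d = ca[j] - ca[i]
            r2 = float(d @ d)
            if r2 > cutoff ** 2:
                continue
            blk = -k * np.outer(d, d) / r2
            H[3 * i:3 * i + 3, 3 * j:3 * j + 3] += blk
            H[3 * j:3 * j + 3, 3 * i:3 * i + 3] += blk
            H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= blk
            H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= blk
    return H


# --------------------------------------------------------------------------
# Point-particle solvent clouds
# --------------------------------------------------------------------------

def generate_solvent_cloud(conf: Conformation, n_water: int, n_tfe: int,
                           box: float | np.ndarray, seed: int,
                           exclusion: float = 2.0) -> Ensemble:
    """Uniform point-particle solvent outside a 2 A exclusion shell.

    Water is an O + 2H triad; TFE a hydrophobic centroid plus a hydroxyl
    site.  ``box`` is either a cube edge length (centred on the peptide) or
    a (3, 2) array of lo/hi bounds.  Counts are exact; raises if the free
    volume cannot host them.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(box):
        c = conf.xyz.mean(0)
        lo, hi = c - box / 2.0, c + box / 2.0
    else:
        b = np.asarray(box, float)
        lo, hi = b[:, 0], b[:, 1]
    if np.any(conf.xyz < lo) or np.any(conf.xyz > hi):
        raise ValueError("box does not enclose the peptide")

    def sample_positions(count):
        placed = []
        tries = 0
        while len(placed) < count:
            tries += 1
            if tries > 20000 * max(count, 1):
                raise ValueError("box too small to place requested solvent counts")
            p = rng.uniform(lo, hi)
            if np.min(np.linalg.norm(conf.xyz - p, axis=1)) < exclusion:
                continue
            placed.append(p)
        return np.array(placed).reshape(count, 3)

    waters = sample_positions(n_water)
    tfes = sample_positions(n_tfe)
    site_xyz, site_names, mol_index, species = [], [], [], []
    mol = 0
    for w in waters:
        species.append("HOH")
        for nm, pos in zip(("OW", "HW1", "HW2"), _water_sites(w, rng)):
            site_xyz.append(pos)
            site_names.append(nm)
            mol_index.append(mol)
        mol += 1
    for tpos in tfes:
        species.append("TFE")
        u = _random_unit(rng)
        for nm, pos in (("CT", tpos), ("OHT", tpos + 1.43 * u)):
            site_xyz.append(pos)
            site_names.append(nm)
            mol_index.append(mol)
        mol += 1
    solvent = Solvent(np.array(site_xyz)[None] if site_xyz else
                      np.zeros((1, 0, 3)),
                      tuple(site_names), np.array(mol_index, dtype=int),
                      tuple(species))
    return Ensemble(conf.topology, conf.xyz[None].copy(), conf.residue_map,
                    solvent=solvent)


def _random_unit(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _water_sites(o: np.ndarray, rng) -> tuple:
    """O plus two H at 0.9572 A separated by 104.5 deg, random orientation."""
    u = _random_unit(rng)
    w = _random_unit(rng)
    w = w - np.dot(w, u) * u
    w /= np.linalg.norm(w)
    half = np.deg2rad(104.5 / 2.0)
    h1 = o + 0.9572 * (np.cos(half) * u + np.sin(half) * w)
    h2 = o + 0.9572 * (np.cos(half) * u - np.sin(half) * w)
    return o, h1, h2


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------

def export_ensemble(ens: Ensemble, directory: str, name: str) -> dict:
    """Write PDB (model 1 topology), DCD trajectory and a JSON ground-truth
    sidecar; returns the file paths."""
    from .ensemble import write_dcd, write_pdb
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {"pdb": d / f"{name}.pdb", "dcd": d / f"{name}.dcd",
             "json": d / f"{name}.json"}
    write_pdb(ens.frame(0), paths["pdb"])
    write_dcd(ens, paths["dcd"])
    meta = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in ens.frame_meta.items()}
    meta["n_frames"] = ens.n_frames
    meta["frame_spacing_ns"] = ens.frame_spacing_ns
    paths["json"].write_text(json.dumps(meta, indent=1))
    return {k: str(v) for k, v in paths.items()}
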