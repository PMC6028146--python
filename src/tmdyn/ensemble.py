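"""Conformations, ensembles, superposition and mean structures.

Coordinates are stored in Angstrom; frame spacing in ns.  Trajectory I/O is
delegated to mdtraj (which uses nm internally; conversion happens at the
boundary).
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import BOND_N_H
from .residues import CA_SELECTION, ONE_TO_THREE, THREE_TO_ONE, ResidueMap, Selection


@dataclass(frozen=True)
class Topology:
    """Minimal shared topology: atom names, per-atom residue index, elements."""

    atom_names: tuple
    atom_resid: np.ndarray           # 0-based construct residue index per atom
    elements: tuple

    def __post_init__(self):
        object.__setattr__(self, "atom_resid",
                           np.asarray(self.atom_resid, dtype=int))
        if len(self.atom_names) != len(self.atom_resid):
            raise ValueError("atom_names and atom_resid length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return int(self.atom_resid.max()) + 1 if self.n_atoms else 0

    def atom_index(self, resid: int, name: str) -> int | None:
        hits = np.flatnonzero(
            (self.atom_resid == resid)
            & np.array([n == name for n in self.atom_names]))
        return int(hits[0]) if hits.size else None

    @classmethod
    def backbone(cls, sequence: str, atom_names=("N", "H", "CA", "C", "O")) -> "Topology":
        """Backbone-only topology for a peptide sequence.

        The N-terminal residue and prolines carry no amide H.
        """
        names, resid, elem = [], [], []
        for i, aa in enumerate(sequence):
            for nm in atom_names:
                if nm == "H" and (i == 0 or aa == "P"):
                    continue
                names.append(nm)
                resid.append(i)
                elem.append(nm[0])
        return cls(tuple(names), np.array(resid), tuple(elem))

    @classmethod
    def calpha(cls, n_residues: int) -> "Topology":
        return cls(("CA",) * n_residues, np.arange(n_residues),
                   ("C",) * n_residues)


@dataclass
class Conformation:
    """A single structure: topology plus coordinates in Angstrom."""

    topology: Topology
    xyz: np.ndarray                      # (n_atoms, 3)
    residue_map: ResidueMap

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (self.topology.n_atoms, 3):
            raise ValueError("coordinate array does not match topology")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")

    def copy(self) -> "Conformation":
        return Conformation(self.topology, self.xyz.copy(), self.residue_map)

    def atom_coords(self, name: str, c99_range: tuple | None = None) -> np.ndarray:
        sel = Selection((name,), c99_range)
        return self.xyz[sel.resolve(self.topology, self.residue_map)]

    def ca(self, c99_range: tuple | None = None) -> np.ndarray:
        return self.atom_coords("CA", c99_range)


@dataclass
class Solvent:
    """Point-particle solvent sites carried alongside a peptide ensemble."""

    xyz: np.ndarray                    # (n_frames, n_sites, 3)
    site_names: tuple                  # e.g. OW, HW1, HW2, CT, OHT
    mol_index: np.ndarray              # molecule id per site
    species: tuple                     # species name per molecule ('HOH'|'TFE')

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.mol_index = np.asarray(self.mol_index, dtype=int)

    @property
    def n_molecules(self) -> int:
        return len(self.species)


@dataclass
class Ensemble:
    """Ordered conformations sharing one topology."""

    topology: Topology
    xyz: np.ndarray                     # (n_frames, n_atoms, 3) Angstrom
    residue_map: ResidueMap
    frame_spacing_ns: float | None = None
    solvent: Solvent | None = None
    frame_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[1] != self.topology.n_atoms:
            raise ValueError("trajectory does not match topology atom count")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    def frame(self, i: int) -> Conformation:
        return Conformation(self.topology, self.xyz[i].copy(), self.residue_map)

    def copy(self) -> "Ensemble":
        return Ensemble(self.topology, self.xyz.copy(), self.residue_map,
                        self.frame_spacing_ns, self.solvent,
                        copy.deepcopy(self.frame_meta))

    def slice_frames(self, idx) -> "Ensemble":
        solv = None
        if self.solvent is not None:
            solv = Solvent(self.solvent.xyz[idx], self.solvent.site_names,
                           self.solvent.mol_index, self.solvent.species)
        return Ensemble(self.topology, self.xyz[idx], self.residue_map,
                        self.frame_spacing_ns, solv, dict(self.frame_meta))


# --------------------------------------------------------------------------
# Rigid-body fitting
# --------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation/translation mapping ``mobile`` onto ``target``.

    Returns (R, t) with ``mobile @ R.T + t`` the least-squares fit.  Standard
    SVD solution with determinant correction to exclude reflections.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("need matching point sets of >=3 atoms")
    mc, tc = mobile.mean(0), target.mean(0)
    H = (mobile - mc).T @ (target - tc)
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    # collinearity guard: two near-zero singular values leave the rotation
    # underdetermined
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise ValueError("selected atoms are (near-)collinear; fit is degenerate")
    return R, tc - R @ mc


def _fit_frame(frame: np.ndarray, ref: np.ndarray, idx: np.ndarray) -> np.ndarray:
    R, t = kabsch(frame[idx], ref[idx])
    return frame @ R.T + t


def superpose(ens: Ensemble, reference: Conformation,
              selection: Selection = CA_SELECTION) -> Ensemble:
    """Least-squares superpose every frame onto ``reference``.

    A rigid transform per frame: internal geometry is untouched.
    """
    idx_e = selection.resolve(ens.topology, ens.residue_map)
    idx_r = selection.resolve(reference.topology, reference.residue_map)
    if len(idx_e) != len(idx_r):
        raise ValueError("selection cardinality differs between ensemble and reference")
    out = ens.copy()
    ref_xyz = reference.xyz[idx_r]
    for f in range(out.n_frames):
        R, t = kabsch(out.xyz[f][idx_e], ref_xyz)
        out.xyz[f] = out.xyz[f] @ R.T + t
    return out


def rmsd_to(conf_a: Conformation, conf_b: Conformation,
            selection: Selection = CA_SELECTION) -> float:
    """Least-squares superposed RMSD (A) between two structures."""
    xa = conf_a.xyz[selection.resolve(conf_a.topology, conf_a.residue_map)]
    xb = conf_b.xyz[selection.resolve(conf_b.topology, conf_b.residue_map)]
    if xa.shape != xb.shape:
        raise ValueError("selection cardinality mismatch")
    R, t = kabsch(xa, xb)
    d = xa @ R.T + t - xb
    return float(np.sqrt((d ** 2).sum() / len(xa)))


def iterative_mean_structure(ens: Ensemble,
                             selection: Selection = CA_SELECTION,
                             tol: float = 1e-6,
                             max_iter: int = 50):
    """Fixed point of (superpose onto current mean -> average coordinates).

    Returns ``(mean_conf, info)`` where ``info`` records iterations and a
    convergence flag.  The RMSD change of the mean between iterations is the
    convergence measure.
    """
    if ens.n_frames < 2:
        raise ValueError("need >=2 frames for a mean structure")
    idx = selection.resolve(ens.topology, ens.residue_map)
    work = ens.copy()
    # initialise from the first frame: a plain coordinate average of
    # unaligned frames can be degenerate (e.g. two frames related by a
    # 180 degree rotation average to a near-collinear point set)
    mean = work.xyz[0].copy()
    converged, n_it = False, 0
    for n_it in range(1, max_iter + 1):
        for f in range(work.n_frames):
            work.xyz[f] = _fit_frame(work.xyz[f], mean, idx)
        new_mean = work.xyz.mean(axis=0)
        # align new mean onto old before measuring the change
        aligned = _fit_frame(new_mean, mean, idx)
        change = np.sqrt(((aligned[idx] - mean[idx]) ** 2).sum(1).mean())
        mean = new_mean
        if change < tol:
            converged = True
            break
    conf = Conformation(ens.topology, mean, ens.residue_map)
    return conf, {"iterations": n_it, "converged": converged, "last_change": change}


# --------------------------------------------------------------------------
# Amide hydrogen reconstruction
# --------------------------------------------------------------------------

def place_amide_hydrogen(c_prev: np.ndarray, n: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """H 1.01 A from N, in the C(i-1)-N-CA plane, opposite their bisector."""
    u = c_prev - n
    v = ca - n
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    d = -(u + v)
    d /= np.linalg.norm(d)
    return n + BOND_N_H * d


def reconstruct_amide_hydrogens(ens: Ensemble) -> Ensemble:
    """Add missing backbone amide hydrogens geometrically.

    Every residue with a defined amide (all but the N-terminal residue and
    prolines) gets an H if none is present.  Returns a new ensemble.
    """
    top = ens.topology
    missing = []
    for r in range(top.n_residues):
        aa = ens.residue_map.sequence[r]
        if r == 0 or aa == "P":
            continue
        if top.atom_index(r, "H") is None:
            need = [top.atom_index(r - 1, "C"), top.atom_index(r, "N"),
                    top.atom_index(r, "CA")]
            if any(i is None for i in need):
                raise ValueError(f"cannot reconstruct H at residue index {r}: "
                                 "backbone incomplete")
            missing.append((r, need))
    if not missing:
        return ens
    names = list(top.atom_names)
    resid = list(top.atom_resid)
    elem = list(top.elements)
    # insert H after the residue's N
    inserts = []
    for r, (ic, inn, ica) in missing:
        inserts.append((inn + 1, r, (ic, inn, ica)))
    inserts.sort(reverse=True)
    new_xyz = ens.xyz.copy()
    for pos, r, (ic, inn, ica) in inserts:
        names.insert(pos, "H")
        resid.insert(pos, r)
        elem.insert(pos, "H")
        h = np.stack([
            place_amide_hydrogen(new_xyz[f, ic], new_xyz[f, inn], new_xyz[f, ica])
            for f in range(new_xyz.shape[0])])
        new_xyz = np.insert(new_xyz, pos, h, axis=1)
    new_top = Topology(tuple(names), np.array(resid), tuple(elem))
    return Ensemble(new_top, new_xyz, ens.residue_map, ens.frame_spacing_ns,
                    ens.solvent, dict(ens.frame_meta))


# --------------------------------------------------------------------------
# I/O (mdtraj-backed)
# --------------------------------------------------------------------------

def _mdtraj_topology(topology: Topology, residue_map: ResidueMap):
    import mdtraj as md
    top = md.Topology()
    chain = top.add_chain()
    residues = []
    for r in range(topology.n_residues):
        code = residue_map.sequence[r]
        res = top.add_residue(ONE_TO_THREE.get(code, "UNK"), chain, resSeq=r + 1)
        residues.append(res)
    from mdtraj.core import element as mdel
    for i in range(topology.n_atoms):
        e = topology.elements[i]
        elem = mdel.get_by_symbol(e if e != "X" else "C")
        top.add_atom(topology.atom_names[i], elem,
                     residues[int(topology.atom_resid[i])])
    return top


def load_ensemble(topology_path: str, trajectory_path: str | None = None,
                  selection: Selection | None = None, stride: int = 1,
                  residue_map: ResidueMap | None = None,
                  frame_spacing_ns: float | None = None) -> Ensemble:
    """Read a PDB topology plus an optional DCD/XTC trajectory.

    ``stride`` keeps frames 0, stride, 2*stride, ...  If no residue map is
    given, a KKW-prefixed sequence is mapped as the C99 construct, anything
    else linearly starting at residue 29 (the helix start of the C99 TMD).
    """
    import mdtraj as md
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if trajectory_path is None:
        traj = md.load(topology_path, stride=stride)
    else:
        try:
            traj = md.load(trajectory_path, top=topology_path, stride=stride)
        except Exception as exc:
            raise ValueError(
                f"failed to read trajectory against topology: {exc}") from exc
    seq = "".join(THREE_TO_ONE.get(r.name, "X") for r in traj.topology.residues)
    if residue_map is None:
        if seq.startswith("KKW"):
            residue_map = ResidueMap.c99_construct(seq)
        else:
            residue_map = ResidueMap.linear(seq, start=29)
    names = tuple(a.name for a in traj.topology.atoms)
    resid = np.array([a.residue.index for a in traj.topology.atoms])
    elems = tuple((a.element.symbol if a.element is not None else "X")
                  for a in traj.topology.atoms)
    topo = Topology(names, resid, elems)
    xyz = np.asarray(traj.xyz, dtype=float) * 10.0   # nm -> A
    if frame_spacing_ns is None and traj.timestep:
        frame_spacing_ns = float(traj.timestep) / 1000.0  # ps -> ns
    ens = Ensemble(topo, xyz, residue_map, frame_spacing_ns=frame_spacing_ns)
    if selection is not None:
        idx = selection.resolve(topo, residue_map)
        sub = Topology(tuple(names[i] for i in idx), resid[idx],
                       tuple(elems[i] for i in idx))
        ens = Ensemble(sub, xyz[:, idx], residue_map, frame_spacing_ns)
    return ens


def to_mdtraj(obj):
    """Convert a Conformation or Ensemble to an mdtraj Trajectory."""
    import mdtraj as md
    if isinstance(obj, Conformation):
        xyz = obj.xyz[None]
        top = _mdtraj_topology(obj.topology, obj.residue_map)
    else:
        xyz = obj.xyz
        top = _mdtraj_topology(obj.topology, obj.residue_map)
    return md.Trajectory(np.asarray(xyz) / 10.0, top)


def write_pdb(obj, path: str) -> None:
    """Write a Conformation (single model) or Ensemble (multi-model PDB)."""
    to_mdtraj(obj).save_pdb(str(path))


def write_dcd(ens: Ensemble, path: str) -> None:
    to_mdtraj(ens).save_dcd(str(path))
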