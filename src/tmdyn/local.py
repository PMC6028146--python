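"""Per-residue structural and dynamic metrics.

H-bond occupancies (alpha i->i+4 and 3_10 i->i+3), carbonyl packing scores,
water coordination, backbone dihedrals (circular statistics), the
differential-geometric rise per residue, arc lengths, RMSF, solvent-shell
mole fractions and convergence diagnostics.  Statistical errors come from
block averaging (5 non-overlapping blocks by default).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import Conformation, Ensemble, iterative_mean_structure, superpose
from .residues import Selection


# --------------------------------------------------------------------------
# Profiles and block averaging
# --------------------------------------------------------------------------

def block_sem(series: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of the mean from non-overlapping block averages."""
    series = np.asarray(series, float)
    if n_blocks < 2 or len(series) < 2 * n_blocks:
        return float("nan")
    usable = (len(series) // n_blocks) * n_blocks
    means = series[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


@dataclass
class ResidueProfile:
    """A per-residue scalar track with block-averaged standard errors.

    ``values`` is NaN (and ``defined`` False) where the metric does not
    exist, e.g. at chain termini; undefined entries are flagged, never
    zero-filled.
    """

    name: str
    units: str
    construct_index: np.ndarray
    c99_numbers: list
    values: np.ndarray
    sem: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def value_at(self, c99_number: int) -> float:
        return float(self.values[self.c99_numbers.index(c99_number)])

    def as_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "construct_index": self.construct_index,
            "c99_residue": self.c99_numbers,
            "metric": self.name,
            "value": self.values,
            "sem": self.sem,
            "units": self.units,
        })


def _profile(ens, name, units, per_frame: np.ndarray, n_blocks=5) -> ResidueProfile:
    """Assemble a profile from a (frames, residues) per-frame matrix."""
    if per_frame.ndim == 2:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            vals = np.nanmean(per_frame, axis=0)
    else:
        vals = per_frame
    if per_frame.ndim == 2:
        sem = np.array([block_sem(per_frame[:, r], n_blocks)
                        if np.isfinite(per_frame[:, r]).all() else np.nan
                        for r in range(per_frame.shape[1])])
    else:
        sem = np.full_like(vals, np.nan)
    n = ens.residue_map.n_residues
    return ResidueProfile(name, units, np.arange(n),
                          list(ens.residue_map.numbers), vals, sem)


# --------------------------------------------------------------------------
# Hydrogen bonds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriterion:
    """Geometric H-bond definition: H...O distance and N-H...O linearity."""

    distance_cutoff: float = 2.6       # A, closed when d <= cutoff
    angle_tolerance: float = 60.0      # deg about 180

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0.0 < self.angle_tolerance <= 90.0):
            raise ValueError("angle tolerance must be in (0, 90] deg")


@dataclass
class OccupancyProfile:
    """Alpha (i->i+4), 3_10 (i->i+3) and combined H-bond occupancies.

    Occupancy is assigned to the carbonyl (acceptor) residue i.  ``closed``
    holds the frame-resolved record, shape (frames, residues, 2) with the
    last axis ordered (alpha, three10); NaN-valued occupancies mark
    carbonyls without a defined partner.
    """

    construct_index: np.ndarray
    c99_numbers: list
    alpha: np.ndarray
    three10: np.ndarray
    combined: np.ndarray
    sem_alpha: np.ndarray
    sem_three10: np.ndarray
    sem_combined: np.ndarray
    closed: np.ndarray

    def as_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "construct_index": self.construct_index,
            "c99_residue": self.c99_numbers,
            "alpha": self.alpha, "alpha_sem": self.sem_alpha,
            "three10": self.three10, "three10_sem": self.sem_three10,
            "combined": self.combined, "combined_sem": self.sem_combined,
        })


def _hbond_closed(ens: Ensemble, i_o: int, i_h: int, i_n: int,
                  crit: HBondCriterion) -> np.ndarray:
    o = ens.xyz[:, i_o]
    h = ens.xyz[:, i_h]
    n = ens.xyz[:, i_n]
    d = np.linalg.norm(o - h, axis=1)
    vn = n - h
    vo = o - h
    cosang = (vn * vo).sum(1) / (np.linalg.norm(vn, axis=1)
                                 * np.linalg.norm(vo, axis=1))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    # N-H...O angle within 180 +/- tolerance; ties on the distance boundary
    # count as closed (strict <=)
    return (d <= crit.distance_cutoff) & (np.abs(180.0 - ang) <= crit.angle_tolerance)


def hbond_occupancy(ens: Ensemble, criterion: HBondCriterion = HBondCriterion(),
                    n_blocks: int = 5) -> OccupancyProfile:
    """Intra-helical H-bond occupancies per carbonyl residue.

    The bond from carbonyl O_i is closed in a frame when either the alpha
    partner (amide H of i+4) or the 3_10 partner (i+3) satisfies the
    criterion.
    """
    top = ens.topology
    n_res = ens.residue_map.n_residues
    F = ens.n_frames
    closed = np.full((F, n_res, 2), False)
    has = np.full((n_res, 2), False)
    for r in range(n_res):
        i_o = top.atom_index(r, "O")
        if i_o is None:
            continue
        for k, off in enumerate((4, 3)):        # (alpha, three10)
            rp = r + off
            if rp >= n_res:
                continue
            i_h = top.atom_index(rp, "H")
            i_n = top.atom_index(rp, "N")
            if i_h is None or i_n is None:
                continue
            closed[:, r, k] = _hbond_closed(ens, i_o, i_h, i_n, criterion)
            has[r, k] = True
    either = closed.any(axis=2)
    defined = has.any(axis=1)

    def occ(mat, mask):
        v = mat.mean(axis=0).astype(float)
        v[~mask] = np.nan
        s = np.array([block_sem(mat[:, r], n_blocks) if mask[r] else np.nan
                      for r in range(n_res)])
        return v, s

    a, sa = occ(closed[:, :, 0], has[:, 0])
    t, st = occ(closed[:, :, 1], has[:, 1])
    c, sc = occ(either, defined)
    return OccupancyProfile(np.arange(n_res), list(ens.residue_map.numbers),
                            a, t, c, sa, st, sc, closed)


# --------------------------------------------------------------------------
# Packing score
# --------------------------------------------------------------------------

def packing_score(ens: Ensemble, n_blocks: int = 5,
                  clash_distance: float = 0.5) -> ResidueProfile:
    """Cut-off-free packing of each carbonyl oxygen, reported x100.

    S_i = sum over all peptide atoms j outside residue i of r_ij^-6,
    measured from the carbonyl O of residue i.  Frames containing an
    overlapping pair (r < 0.5 A) are rejected with diagnostics.
    """
    top = ens.topology
    n_res = ens.residue_map.n_residues
    F = ens.n_frames
    per_frame = np.full((F, n_res), np.nan)
    rejected = []
    for f in range(F):
        xyz = ens.xyz[f]
        bad = False
        for r in range(n_res):
            i_o = top.atom_index(r, "O")
            if i_o is None:
                continue
            other = top.atom_resid != r
            d = np.linalg.norm(xyz[other] - xyz[i_o], axis=1)
            if (d < clash_distance).any():
                bad = True
                break
            per_frame[f, r] = 100.0 * float((d ** -6).sum())
        if bad:
            per_frame[f] = np.nan
            rejected.append(f)
    if rejected and len(rejected) == F:
        raise ValueError(f"all frames rejected for atom clashes: {rejected[:5]}...")
    ok = ~np.isin(np.arange(F), rejected)
    prof = _profile(ens, "packing_score", "x100 A^-6", per_frame[ok], n_blocks)
    prof.rejected_frames = rejected
    return prof


# --------------------------------------------------------------------------
# Water coordination
# --------------------------------------------------------------------------

def water_coordination(ens: Ensemble, criterion_distance: float = 2.6,
                       per_molecule_cap: bool = False,
                       n_blocks: int = 5) -> ResidueProfile:
    """Frame-averaged count of water hydrogens within 2.6 A of carbonyl O.

    With ``per_molecule_cap`` each water counts at most once per carbonyl.
    Raises when the ensemble carries no solvent (distinct from a zero
    count).
    """
    if ens.solvent is None:
        raise ValueError("ensemble has no solvent; water coordination undefined")
    solv = ens.solvent
    is_wat_h = np.array([
        solv.species[solv.mol_index[s]] == "HOH" and
        solv.site_names[s].startswith("H")
        for s in range(len(solv.site_names))])
    h_idx = np.flatnonzero(is_wat_h)
    h_mol = solv.mol_index[h_idx]
    top = ens.topology
    n_res = ens.residue_map.n_residues
    F = ens.n_frames
    per_frame = np.full((F, n_res), np.nan)
    for r in range(n_res):
        i_o = top.atom_index(r, "O")
        if i_o is None:
            continue
        for f in range(F):
            sf = min(f, solv.xyz.shape[0] - 1)   # static cloud reused per frame
            if h_idx.size == 0:
                per_frame[f, r] = 0.0
                continue
            d = np.linalg.norm(solv.xyz[sf, h_idx] - ens.xyz[f, i_o], axis=1)
            hit = d <= criterion_distance
            if per_molecule_cap:
                per_frame[f, r] = float(len(np.unique(h_mol[hit])))
            else:
                per_frame[f, r] = float(hit.sum())
    return _profile(ens, "water_coordination", "count", per_frame, n_blocks)


# --------------------------------------------------------------------------
# Backbone dihedrals
# --------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3):
    """Signed dihedral angle in degrees; vectorised over leading axes."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - (b0 * b1n).sum(-1, keepdims=True) * b1n
    w = b2 - (b2 * b1n).sum(-1, keepdims=True) * b1n
    x = (v * w).sum(-1)
    y = (np.cross(b1n, v) * w).sum(-1)
    return np.degrees(np.arctan2(y, x))


def _circular_mean_sd(deg: np.ndarray):
    rad = np.deg2rad(deg)
    z = np.exp(1j * rad).mean()
    mean = np.degrees(np.angle(z))
    R = abs(z)
    sd = np.degrees(np.sqrt(-2.0 * np.log(max(R, 1e-300))))
    return mean, sd


def backbone_dihedrals(ens: Ensemble):
    """Circular mean and circular SD of phi and psi per residue (deg).

    Returns ``(phi_profile, psi_profile)``; the SEM slot carries the
    circular standard deviation.  Terminal residues without the required
    atoms are flagged undefined.
    """
    top = ens.topology
    n_res = ens.residue_map.n_residues
    out = []
    for name in ("phi", "psi"):
        vals = np.full(n_res, np.nan)
        sds = np.full(n_res, np.nan)
        for r in range(n_res):
            if name == "phi":
                ids = (top.atom_index(r - 1, "C") if r > 0 else None,
                       top.atom_index(r, "N"), top.atom_index(r, "CA"),
                       top.atom_index(r, "C"))
            else:
                ids = (top.atom_index(r, "N"), top.atom_index(r, "CA"),
                       top.atom_index(r, "C"),
                       top.atom_index(r + 1, "N") if r + 1 < n_res else None)
            if any(i is None for i in ids):
                continue
            series = dihedral(*(ens.xyz[:, i] for i in ids))
            vals[r], sds[r] = _circular_mean_sd(series)
        out.append(ResidueProfile(name, "deg", np.arange(n_res),
                                  list(ens.residue_map.numbers), vals, sds))
    return tuple(out)


# --------------------------------------------------------------------------
# Rise per residue and arc length
# --------------------------------------------------------------------------

def _rise_profile_single(ca: np.ndarray) -> np.ndarray:
    """Local rise assigned to residue i for the step Cα_i -> Cα_{i+1}.

    bisector b_i = unit((Cα_{i-1}-Cα_i) + (Cα_{i+1}-Cα_i)); local axis =
    unit(b_i × b_{i+1}); rise = |(Cα_{i+1}-Cα_i)·axis|.  Undefined for the
    terminal pairs; degenerate (collinear) geometry yields NaN.
    """
    n = len(ca)
    out = np.full(n, np.nan)
    for i in range(1, n - 2):
        b1 = (ca[i - 1] - ca[i]) + (ca[i + 1] - ca[i])
        b2 = (ca[i] - ca[i + 1]) + (ca[i + 2] - ca[i + 1])
        n1, n2 = np.linalg.norm(b1), np.linalg.norm(b2)
        if n1 < 1e-10 or n2 < 1e-10:
            continue
        a = np.cross(b1 / n1, b2 / n2)
        na = np.linalg.norm(a)
        if na < 1e-10:
            continue
        out[i] = abs(float(np.dot(ca[i + 1] - ca[i], a / na)))
    return out


def rise_per_residue(obj, n_blocks: int = 5) -> ResidueProfile:
    """Differential-geometric rise per residue (A) of a conformation or
    ensemble (frame-averaged with block SEM)."""
    if isinstance(obj, Conformation):
        ca = obj.ca()
        vals = _rise_profile_single(ca)
        n = obj.residue_map.n_residues
        return ResidueProfile("rise_per_residue", "A", np.arange(n),
                              list(obj.residue_map.numbers), vals,
                              np.full(n, np.nan))
    ens: Ensemble = obj
    sel = Selection(("CA",), None)
    idx = sel.resolve(ens.topology, ens.residue_map)
    per_frame = np.stack([_rise_profile_single(ens.xyz[f][idx])
                          for f in range(ens.n_frames)])
    return _profile(ens, "rise_per_residue", "A", per_frame, n_blocks)


def arc_length(obj, from_residue: int, to_residue: int):
    """Helix arc length: sum of local rises between two C99 residues.

    Additive by construction: arc(a,b) + arc(b,c) == arc(a,c).  Returns a
    scalar for a Conformation, a per-frame array for an Ensemble.  Raises
    if the range touches steps with undefined rise.
    """
    rmap = obj.residue_map
    ia, ib = rmap.index_of(from_residue), rmap.index_of(to_residue)
    if ia > ib:
        ia, ib = ib, ia
    single = isinstance(obj, Conformation)
    frames = [obj] if single else [obj.frame(f) for f in range(obj.n_frames)]
    out = np.empty(len(frames))
    for k, conf in enumerate(frames):
        rp = _rise_profile_single(conf.ca())
        steps = rp[ia:ib]
        if np.isnan(steps).any():
            raise ValueError("arc range touches residues with undefined rise")
        out[k] = float(steps.sum())
    return float(out[0]) if single else out


def arc_length_histogram(values: np.ndarray, bin_width: float = 0.1):
    """Histogram of an arc-length distribution with 0.1 A bins."""
    values = np.asarray(values, float)
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges


# --------------------------------------------------------------------------
# RMSF
# --------------------------------------------------------------------------

def rmsf(ens: Ensemble, selection: Selection = Selection(("CA",), None),
         n_blocks: int = 5) -> ResidueProfile:
    """Root mean-square fluctuation (A) about the iterative mean structure.

    The ensemble is superposed onto its iterative mean on the selection
    before fluctuations are measured.
    """
    if ens.n_frames < 2:
        raise ValueError("need >=2 frames for fluctuations")
    mean, _ = iterative_mean_structure(ens, selection)
    sup = superpose(ens, mean, selection)
    idx = selection.resolve(ens.topology, ens.residue_map)
    mu = sup.xyz[:, idx].mean(axis=0)
    sq = ((sup.xyz[:, idx] - mu) ** 2).sum(axis=2)     # (F, n_sel)
    n_res = ens.residue_map.n_residues
    vals = np.full(n_res, np.nan)
    sem = np.full(n_res, np.nan)
    resid = ens.topology.atom_resid[idx]
    for r in np.unique(resid):
        cols = sq[:, resid == r].mean(axis=1)
        vals[r] = float(np.sqrt(cols.mean()))
        sem[r] = block_sem(np.sqrt(cols), n_blocks)
    return ResidueProfile("rmsf", "A", np.arange(n_res),
                          list(ens.residue_map.numbers), vals, sem)


# --------------------------------------------------------------------------
# Solvent shells
# --------------------------------------------------------------------------

def solvent_shell_fractions(ens: Ensemble,
                            shells=((0.0, 4.5), (4.5, 6.5), (6.5, 10.0)),
                            bulk_reference: float | None = None):
    """Per-residue, per-shell change of the water mole fraction vs bulk.

    Distances are between residue side-chain centres of mass (Cα fallback
    for backbone-only models) and solvent-molecule centres of mass.  The
    bulk fraction defaults to the overall water fraction of the cloud;
    ``bulk_reference`` overrides it (e.g. 0.5 for an equimolar reference).
    Empty shells are NaN-flagged.  Returns a list of ResidueProfile, one
    per shell.
    """
    if ens.solvent is None:
        raise ValueError("ensemble has no solvent")
    solv = ens.solvent
    n_mol = solv.n_molecules
    if n_mol == 0:
        raise ValueError("solvent cloud is empty")
    is_water = np.array([sp == "HOH" for sp in solv.species])
    if bulk_reference is None:
        bulk = float(is_water.mean())
    else:
        bulk = float(bulk_reference)
    top = ens.topology
    n_res = ens.residue_map.n_residues
    F = ens.n_frames
    backbone = {"N", "H", "CA", "C", "O", "OXT"}
    profiles = []
    counts = np.zeros((len(shells), n_res, 2))     # (shell, residue, [water, total])
    for f in range(F):
        sf = min(f, solv.xyz.shape[0] - 1)
        mol_com = np.stack([solv.xyz[sf][solv.mol_index == m].mean(0)
                            for m in range(n_mol)])
        for r in range(n_res):
            mask = top.atom_resid == r
            side = mask & np.array([nm not in backbone for nm in top.atom_names])
            ref_atoms = side if side.any() else (
                mask & np.array([nm == "CA" for nm in top.atom_names]))
            com = ens.xyz[f][ref_atoms].mean(0)
            d = np.linalg.norm(mol_com - com, axis=1)
            for s, (lo, hi) in enumerate(shells):
                inshell = (d > lo) & (d <= hi) if lo > 0 else (d <= hi)
                counts[s, r, 0] += float((inshell & is_water).sum())
                counts[s, r, 1] += float(inshell.sum())
    for s, (lo, hi) in enumerate(shells):
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = counts[s, :, 0] / counts[s, :, 1]
        vals = frac - bulk
        vals[counts[s, :, 1] == 0] = np.nan
        profiles.append(ResidueProfile(
            f"water_fraction_change_{lo:g}-{hi:g}A", "mole fraction",
            np.arange(n_res), list(ens.residue_map.numbers), vals,
            np.full(n_res, np.nan)))
    return profiles


# --------------------------------------------------------------------------
# Convergence diagnostics
# --------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    window_lengths: np.ndarray           # frames
    window_rmsd: np.ndarray              # mean RMSD of window means vs full mean
    hbond_residues: list                 # C99 numbers with a defined alpha bond
    hbond_corr_times: np.ndarray         # first zero crossing (ns, or frames)
    n_blocks: int
    frame_spacing_ns: float | None


def _first_zero_crossing(series: np.ndarray) -> float:
    x = series - series.mean()
    v = float((x * x).mean())
    if v <= 0:
        return 0.0
    n = len(x)
    ac = np.correlate(x, x, mode="full")[n - 1:] / (v * n)
    below = np.flatnonzero(ac <= 0)
    return float(below[0]) if below.size else float(n)


def convergence_diagnostics(ens: Ensemble, n_blocks: int = 5,
                            selection: Selection = Selection(("CA",), None),
                            criterion: HBondCriterion = HBondCriterion()) -> ConvergenceReport:
    """Window-mean RMSD curve plus alpha-H-bond length correlation times.

    (a) mean structures over non-overlapping windows of doubling length,
    RMSD to the full-trajectory mean; (b) autocorrelation of O...H(i+4)
    length fluctuations, correlation time = first passage through zero.
    """
    F = ens.n_frames
    if F < 2 * n_blocks:
        raise ValueError("too few frames per block")
    from .ensemble import rmsd_to
    mean, _ = iterative_mean_structure(ens, selection)
    sup = superpose(ens, mean, selection)
    lengths, rmsds = [], []
    L = 2
    while L <= F // 2:
        vals = []
        for s in range(0, F - L + 1, L):
            wmean = Conformation(ens.topology, sup.xyz[s:s + L].mean(0),
                                 ens.residue_map)
            vals.append(rmsd_to(wmean, mean, selection))
        lengths.append(L)
        rmsds.append(float(np.mean(vals)))
        L *= 2
    top = ens.topology
    n_res = ens.residue_map.n_residues
    res_out, taus = [], []
    spacing = ens.frame_spacing_ns
    for r in range(n_res):
        i_o = top.atom_index(r, "O")
        i_h = top.atom_index(r + 4, "H") if r + 4 < n_res else None
        if i_o is None or i_h is None:
            continue
        d = np.linalg.norm(ens.xyz[:, i_o] - ens.xyz[:, i_h], axis=1)
        tau = _first_zero_crossing(d)
        if spacing is not None:
            tau *= spacing
        num = ens.residue_map.number_of(r)
        res_out.append(num if num is not None else -r)
        taus.append(tau)
    return ConvergenceReport(np.array(lengths), np.array(rmsds), res_out,
                             np.array(taus), n_blocks, spacing)
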