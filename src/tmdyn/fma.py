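"""Partial-least-squares functional mode analysis (PLS-FMA).

Finds the collective backbone motion whose projection best predicts a
scalar order parameter (here: counts of closed backbone H-bonds over a
carbonyl region).  The model is fit on the chronological first half of the
frames and cross-validated on the second half; the reported mode is the
ensemble-weighted maximally correlated motion (ewMCM): the PLS regression
direction rescaled by the ensemble covariance and unit-normalised, with the
sign fixed so that increasing projection increases the order parameter.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BACKBONE_HEAVY
from .ensemble import Conformation, Ensemble, iterative_mean_structure, superpose
from .local import HBondCriterion, hbond_occupancy
from .residues import Selection

# Carbonyl regions of the two functional order parameters: region I spans
# the central hinge (carbonyls G33-G38), region II the gamma-site region
# (carbonyls V40-T43).
REGIONS = {"region1": (33, 38), "region2": (40, 43)}

DEFAULT_FMA_RANGE = (28, 54)        # heavy backbone atoms of K28-K54


@dataclass
class OrderParameterSeries:
    """Per-frame count of closed H-bonds over a named carbonyl set."""

    values: np.ndarray
    region: tuple
    carbonyls: list                  # C99 numbers

    @property
    def n_bonds(self) -> int:
        return len(self.carbonyls)


def order_parameter(ens: Ensemble, region="region1",
                    criterion: HBondCriterion = HBondCriterion()) -> OrderParameterSeries:
    """Closed-H-bond count (alpha or 3_10) per frame over a carbonyl region."""
    if isinstance(region, str):
        region = REGIONS[region]
    first, last = region
    rmap = ens.residue_map
    idx = rmap.indices_of_range(first, last)
    occ = hbond_occupancy(ens, criterion)
    closed_either = occ.closed.any(axis=2)          # (F, n_res)
    defined = np.isfinite(occ.combined)
    if not defined[idx].all():
        raise ValueError("region contains carbonyls without defined partners")
    series = closed_either[:, idx].sum(axis=1).astype(float)
    return OrderParameterSeries(series, (first, last),
                                list(range(first, last + 1)))


@dataclass
class FunctionalMode:
    """ewMCM vector over heavy backbone atoms plus fit/validation quality."""

    vector: np.ndarray               # unit-normalised, length 3*n_atoms
    atom_indices: np.ndarray         # topology atom indices of the mapping
    atom_names: list
    atom_residues: list              # C99 numbers per mapped atom
    n_components: int
    r_m: float                       # training correlation
    r_c: float                       # cross-validation correlation
    mean_xyz: np.ndarray             # mean structure over the mapped atoms
    projections: np.ndarray          # training-half projections onto the mode

    def ca_subvector(self) -> np.ndarray:
        """Unit-normalised restriction of the mode to its Cα components."""
        mask = np.repeat(np.array([n == "CA" for n in self.atom_names]), 3)
        v = self.vector[mask]
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ValueError("mode has no Cα component")
        return v / nv


def _fma_matrix(ens: Ensemble, residue_range):
    sel = Selection(BACKBONE_HEAVY, residue_range)
    idx = sel.resolve(ens.topology, ens.residue_map)
    X = ens.xyz[:, idx].reshape(ens.n_frames, -1)
    names = [ens.topology.atom_names[i] for i in idx]
    resnums = [ens.residue_map.number_of(int(ens.topology.atom_resid[i]))
               for i in idx]
    return X, idx, names, resnums


def _pearson(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def fit_fma(ens: Ensemble, y: OrderParameterSeries | np.ndarray,
            n_components: int = 13, split: float = 0.5,
            residue_range=None, presuperposed: bool = False) -> FunctionalMode:
    """PLS regression of the order parameter on centred backbone coordinates.

    The chronological first ``split`` fraction of frames trains the model
    (R_m); the remainder cross-validates it (R_c).  Predictors default to
    the heavy backbone atoms of the mapped range (K28-K54 where available).
    """
    from sklearn.cross_decomposition import PLSRegression
    yv = y.values if isinstance(y, OrderParameterSeries) else np.asarray(y, float)
    if len(yv) != ens.n_frames:
        raise ValueError("order-parameter length does not match frame count")
    if np.ptp(yv) == 0:
        raise ValueError("order parameter is constant; nothing to model")
    if residue_range is None:
        mapped = ens.residue_map.mapped_numbers
        residue_range = (max(DEFAULT_FMA_RANGE[0], mapped[0]),
                         min(DEFAULT_FMA_RANGE[1], mapped[-1]))
        if residue_range[0] > residue_range[1]:
            # numbering does not intersect the C99 default: use everything
            residue_range = (mapped[0], mapped[-1])
    work = ens
    if not presuperposed:
        mean, _ = iterative_mean_structure(ens)
        work = superpose(ens, mean)
    X, idx, names, resnums = _fma_matrix(work, residue_range)
    n_train = int(round(split * len(yv)))
    if n_train < 2 or len(yv) - n_train < 2:
        raise ValueError("split leaves too few frames")
    Xtr, Xval = X[:n_train], X[n_train:]
    ytr, yval = yv[:n_train], yv[n_train:]
    rank = min(Xtr.shape[0] - 1, Xtr.shape[1])
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xtr, ytr)
    r_m = _pearson(pls.predict(Xtr).ravel(), ytr)
    r_c = _pearson(pls.predict(Xval).ravel(), yval)
    beta = np.asarray(pls.coef_).reshape(-1)
    # ensemble weighting: rescale the regression direction by the training
    # covariance, i.e. the maximally correlated *motion* actually present
    Xc = Xtr - Xtr.mean(axis=0)
    mode = Xc.T @ (Xc @ beta) / (len(Xtr) - 1)
    nv = np.linalg.norm(mode)
    if nv == 0:
        raise ValueError("degenerate ewMCM (zero covariance along regression direction)")
    mode = mode / nv
    proj = Xc @ mode
    if _pearson(proj, ytr) < 0:
        mode = -mode
        proj = -proj
    return FunctionalMode(mode, idx, names, resnums, n_components,
                          r_m, r_c, X.mean(axis=0), proj)


@dataclass
class ComponentSelection:
    n_components: int | None
    r_m_curve: np.ndarray
    r_c_curve: np.ndarray
    threshold: float
    converged: bool


def select_components(ens: Ensemble, y, max_components: int = 20,
                      threshold: float = 0.75, delta: float = 0.01,
                      **fit_kwargs) -> ComponentSelection:
    """Smallest PLS component count with R_m above threshold and converged.

    Convergence means the R_m increment falls below ``delta``.  If the
    threshold is never reached the full curve is returned with a flag.
    """
    r_m, r_c = [], []
    for k in range(1, max_components + 1):
        try:
            fm = fit_fma(ens, y, n_components=k, **fit_kwargs)
        except ValueError:
            break
        r_m.append(fm.r_m)
        r_c.append(fm.r_c)
    r_m = np.array(r_m)
    r_c = np.array(r_c)
    chosen = None
    for i in range(len(r_m)):
        if r_m[i] > threshold and (i == 0 or r_m[i] - r_m[i - 1] < delta):
            chosen = i + 1
            break
    return ComponentSelection(chosen, r_m, r_c, threshold, chosen is not None)


def ewmcm_interpolation(fm: FunctionalMode, ens: Ensemble,
                        n_steps: int = 10) -> Ensemble:
    """Structures along the ewMCM between the 1st/99th projection percentiles.

    Returns an ensemble over the mode's atom subset; its first and last
    frames are the low/high-occupancy endpoint structures used for hinge
    analysis.  ``n_steps=1`` returns the mean structure.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    from .ensemble import Topology
    top = ens.topology
    sub = Topology(tuple(top.atom_names[i] for i in fm.atom_indices),
                   top.atom_resid[fm.atom_indices],
                   tuple(top.elements[i] for i in fm.atom_indices))
    lo, hi = np.percentile(fm.projections, [1.0, 99.0])
    if hi - lo <= 0:
        raise ValueError("degenerate projection range")
    ts = np.array([0.0]) if n_steps == 1 else np.linspace(lo, hi, n_steps)
    frames = fm.mean_xyz[None] + ts[:, None] * fm.vector[None]
    return Ensemble(sub, frames.reshape(n_steps, -1, 3), ens.residue_map,
                    frame_meta={"projection": ts})


@dataclass
class ModeSimilarity:
    matrix: np.ndarray               # |inner product|, unit diagonal
    linkage: np.ndarray              # scipy complete-linkage on 1 - |dot|
    labels: list


def mode_similarity(modes, labels=None) -> ModeSimilarity:
    """Pairwise |inner product| of ewMCM vectors + complete-linkage clustering."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform
    if len(modes) < 2:
        raise ValueError("need >=2 modes")
    dim = len(modes[0].vector)
    for m in modes:
        if len(m.vector) != dim or list(m.atom_names) != list(modes[0].atom_names):
            raise ValueError("modes use different atom mappings")
    V = np.stack([m.vector for m in modes])
    M = np.abs(V @ V.T)
    np.fill_diagonal(M, 1.0)
    M = np.clip(M, 0.0, 1.0)
    D = squareform(1.0 - M, checks=False)
    Z = linkage(D, method="complete")
    return ModeSimilarity(M, Z, labels or [f"mode{i}" for i in range(len(modes))])
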