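"""Quasi-harmonic dynamic perturbation-response scanning (PRS).

The pre-bound peptide is described by the quasi-harmonic covariance C_u of
its Cα fluctuations; the enzyme is an implicit linear chain of binding
sites.  Weak isotropic springs gamma couple chosen TMD residues to enzyme
sites, strong springs kappa chain neighbouring enzyme sites.  Integrating
the enzyme out (Schur complement over the enzyme block of the combined
Hessian) yields an effective stiffness increment delta_H acting on the
peptide; the bound-state covariance follows from

    C_b = (I + C_u . delta_H / k_B T)^-1 . C_u

which propagates the perturbation strictly inside the sampled fluctuation
space (range of C_u) and requires no pseudo-inversion.  For a full-rank
covariance this is algebraically identical to inverting the effective
Hessian H_b = k_B T C_u^-1 + delta_H.

Sign bookkeeping: couplings enter the combined Hessian as off-diagonal
blocks -gamma*E with diagonal closure making every row/column of the
interacting system sum to zero; the eliminated increment
delta_H = D - H_SE H_EE^-1 H_ES is positive semidefinite (binding can only
stiffen), as the brute-force full-system oracle in the test-suite checks.

A single free enzyme site attached by one spring is eliminated exactly to
delta_H = 0 (the site simply follows the peptide); meaningful single-site
perturbations therefore hold the enzyme site fixed ("grounded"), giving
delta_H = gamma*E at the bound residue.  The residue-by-residue scan uses
grounded sites.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, kbt
from .ensemble import Ensemble, iterative_mean_structure, superpose
from .residues import Selection


# --------------------------------------------------------------------------
# Covariance / Hessian containers
# --------------------------------------------------------------------------

@dataclass
class CovarianceMatrix:
    """3N x 3N covariance (A^2) of Cα fluctuations with residue labels."""

    matrix: np.ndarray
    residues: list                       # C99 numbers, length N
    temperature: float = DEFAULT_TEMPERATURE_K
    provenance: str = "analytic"         # 'ensemble' | 'analytic'
    n_frames: int | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        n = 3 * len(self.residues)
        if self.matrix.shape != (n, n):
            raise ValueError("covariance dimension does not match residue list")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def msf(self) -> np.ndarray:
        """Per-residue mean-square fluctuation: trace of the 3x3 diagonal block."""
        d = np.diag(self.matrix)
        return d.reshape(-1, 3).sum(axis=1)

    def block_index(self, residue: int) -> int:
        try:
            return self.residues.index(residue)
        except ValueError:
            raise KeyError(f"residue {residue} not in covariance selection")


@dataclass
class Hessian:
    """Effective Hessian (kcal mol^-1 A^-2) with pseudo-inversion provenance."""

    matrix: np.ndarray
    residues: list
    temperature: float
    retained_rank: int
    removed_modes: int


def covariance_from_ensemble(ens: Ensemble,
                             selection: Selection = Selection(("CA",), None),
                             presuperposed: bool = False) -> CovarianceMatrix:
    """Quasi-harmonic covariance <dx dx^T> about the iterative mean."""
    work = ens
    if not presuperposed:
        mean, _ = iterative_mean_structure(ens, selection)
        work = superpose(ens, mean, selection)
    idx = selection.resolve(ens.topology, ens.residue_map)
    # the covariance is labelled by C99 numbers; tag residues carry none
    idx = np.array([i for i in idx
                    if ens.residue_map.number_of(int(ens.topology.atom_resid[i]))
                    is not None])
    X = work.xyz[:, idx].reshape(work.n_frames, -1)
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / work.n_frames
    residues = [ens.residue_map.number_of(int(ens.topology.atom_resid[i]))
                for i in idx]
    if work.n_frames < X.shape[1]:
        import warnings
        warnings.warn(f"covariance rank-limited: {work.n_frames} frames for "
                      f"{X.shape[1]} coordinates", stacklevel=2)
    return CovarianceMatrix(C, residues, provenance="ensemble",
                            n_frames=work.n_frames)


def hessian_from_covariance(C: CovarianceMatrix,
                            temperature: float | None = None,
                            n_removed: int = 6,
                            rel_tol: float = 1e-10) -> Hessian:
    """Spectral pseudo-inverse scaled by k_BT.

    The ``n_removed`` smallest modes (rigid-body remnants of an
    ensemble-derived covariance) plus anything below ``rel_tol`` times the
    largest eigenvalue are excluded.  Use ``n_removed=0`` for analytic
    full-rank covariances.
    """
    T = temperature if temperature is not None else C.temperature
    w, v = np.linalg.eigh(C.matrix)
    if w.min() < -rel_tol * max(w.max(), 1.0):
        raise ValueError(f"covariance has negative eigenvalue {w.min():g}")
    order = np.argsort(w)              # ascending
    keep = order[n_removed:] if n_removed else order
    keep = keep[w[keep] > rel_tol * w.max()]
    H = kbt(T) * (v[:, keep] / w[keep]) @ v[:, keep].T
    return Hessian(H, list(C.residues), T, len(keep),
                   3 * C.n_residues - len(keep))


def covariance_from_hessian(H: Hessian, rel_tol: float = 1e-10) -> CovarianceMatrix:
    """k_BT times the pseudo-inverse of an effective Hessian."""
    w, v = np.linalg.eigh(H.matrix)
    keep = w > rel_tol * w.max()
    C = kbt(H.temperature) * (v[:, keep] / w[keep]) @ v[:, keep].T
    return CovarianceMatrix(C, list(H.residues), H.temperature, "analytic")


# --------------------------------------------------------------------------
# Binding models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingModel:
    """Implicit-enzyme coupling: TMD residues sprung to a chain of sites.

    ``couplings`` maps each bound TMD residue (C99 number) to one enzyme
    site index 0..M-1; gamma is the binding spring, kappa the enzyme
    chain spring (kcal mol^-1 A^-2).  ``grounded`` holds the enzyme sites
    fixed instead of eliminating a free chain.
    """

    couplings: tuple                     # ((residue, site), ...)
    gamma: float = 5.0
    kappa: float = 150.0
    n_sites: int | None = None
    grounded: bool = False
    name: str = "custom"

    def __post_init__(self):
        res = [r for r, _ in self.couplings]
        sites = [s for _, s in self.couplings]
        if len(set(res)) != len(res):
            raise ValueError("each TMD residue may bind at most one enzyme site")
        if len(set(sites)) != len(sites):
            raise ValueError("each enzyme site may bind at most one residue")
        if self.gamma <= 0 and self.gamma != 0.0:
            raise ValueError("gamma must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_sites is None:
            object.__setattr__(self, "n_sites", max(sites) + 1 if sites else 0)

    @classmethod
    def preset(cls, name: str, gamma: float = 5.0, kappa: float = 150.0) -> "BindingModel":
        residues = PRESET_MODELS[name]
        return cls(tuple((r, i) for i, r in enumerate(residues)),
                   gamma=gamma, kappa=kappa, name=name)

    @classmethod
    def single_site(cls, residue: int, gamma: float = 5.0) -> "BindingModel":
        """Grounded single-residue binding used by the PRS scan."""
        return cls(((residue, 0),), gamma=gamma, grounded=True,
                   name=f"single_{residue}")


# Multi-site binding presets: contact patterns probed against the enzyme.
# model5 follows the hypothetical embedding of the N-terminal helix
# (residues G29-G38 inclusive).
PRESET_MODELS = {
    "model1": (37, 38),
    "model2": (33, 37),
    "model3": (38, 42),
    "model4": (35, 39),
    "model5": tuple(range(29, 39)),
}


def binding_increment(model: BindingModel, residues: list) -> np.ndarray:
    """Effective stiffness increment delta_H on the peptide (3N x 3N).

    Assembles the coupling blocks H_SE (-gamma E per coupling), the enzyme
    tridiagonal H_EE (chain springs kappa, diagonal closure summing every
    interaction) and the substrate diagonal correction D, then eliminates
    the enzyme block:  delta_H = D - H_SE H_EE^-1 H_ES.  For grounded
    models delta_H = D.
    """
    N = len(residues)
    M = model.n_sites
    g, k = model.gamma, model.kappa
    if g == 0.0:
        return np.zeros((3 * N, 3 * N))
    D = np.zeros((3 * N, 3 * N))
    pos = {}
    for r, s in model.couplings:
        try:
            i = residues.index(r)
        except ValueError:
            raise KeyError(f"bound residue {r} is outside the Cα selection")
        D[3 * i:3 * i + 3, 3 * i:3 * i + 3] += g * np.eye(3)
        pos[s] = i
    if model.grounded or M == 0:
        return D
    HSE = np.zeros((3 * N, 3 * M))
    HEE = np.zeros((3 * M, 3 * M))
    for s, i in pos.items():
        HSE[3 * i:3 * i + 3, 3 * s:3 * s + 3] = -g * np.eye(3)
        HEE[3 * s:3 * s + 3, 3 * s:3 * s + 3] += g * np.eye(3)
    for m in range(M - 1):
        HEE[3 * m:3 * m + 3, 3 * (m + 1):3 * (m + 1) + 3] = -k * np.eye(3)
        HEE[3 * (m + 1):3 * (m + 1) + 3, 3 * m:3 * m + 3] = -k * np.eye(3)
        HEE[3 * m:3 * m + 3, 3 * m:3 * m + 3] += k * np.eye(3)
        HEE[3 * (m + 1):3 * (m + 1) + 3, 3 * (m + 1):3 * (m + 1) + 3] += k * np.eye(3)
    try:
        X = np.linalg.solve(HEE, HSE.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular enzyme block H_EE: {exc}") from exc
    dH = D - HSE @ X
    return 0.5 * (dH + dH.T)


def assemble_full_hessian(H_ss: np.ndarray, model: BindingModel,
                          residues: list) -> np.ndarray:
    """Explicit combined substrate+enzyme Hessian in block form.

    Oracle-side construction: the substrate block carries the diagonal
    closure, the coupling blocks are -gamma E, the enzyme chain is the
    kappa tridiagonal with closure diagonals.
    """
    N = len(residues)
    M = model.n_sites
    g, k = model.gamma, model.kappa
    full = np.zeros((3 * (N + M), 3 * (N + M)))
    full[:3 * N, :3 * N] = H_ss
    for r, s in model.couplings:
        i = residues.index(r)
        full[3 * i:3 * i + 3, 3 * i:3 * i + 3] += g * np.eye(3)
        full[3 * i:3 * i + 3, 3 * N + 3 * s:3 * N + 3 * s + 3] = -g * np.eye(3)
        full[3 * N + 3 * s:3 * N + 3 * s + 3, 3 * i:3 * i + 3] = -g * np.eye(3)
        full[3 * N + 3 * s:3 * N + 3 * s + 3,
             3 * N + 3 * s:3 * N + 3 * s + 3] += g * np.eye(3)
    for m in range(M - 1):
        a = 3 * N + 3 * m
        b = 3 * N + 3 * (m + 1)
        full[a:a + 3, b:b + 3] += -k * np.eye(3)
        full[b:b + 3, a:a + 3] += -k * np.eye(3)
        full[a:a + 3, a:a + 3] += k * np.eye(3)
        full[b:b + 3, b:b + 3] += k * np.eye(3)
    return full


# --------------------------------------------------------------------------
# Applying a binding model
# --------------------------------------------------------------------------

@dataclass
class PerturbationResult:
    model: BindingModel
    covariance_bound: CovarianceMatrix
    msf_unbound: np.ndarray
    msf_bound: np.ndarray
    delta_msf: np.ndarray                # relative change per the calibration rule
    f_norm_unbound: np.ndarray
    f_norm_bound: np.ndarray
    z_diff: np.ndarray
    significant: np.ndarray              # |Z| > 1
    z_flag: str | None                   # None or reason Z is undefined


def apply_binding(C_u: CovarianceMatrix, model: BindingModel) -> PerturbationResult:
    """Bound-state covariance and fluctuation reorganisation for one model.

    C_b = (I + C_u delta_H / k_BT)^-1 C_u; the perturbation propagates along
    the correlated fluctuations of the pre-bound state.
    """
    dH = binding_increment(model, list(C_u.residues))
    C = C_u.matrix
    kT = kbt(C_u.temperature)
    A = np.eye(C.shape[0]) + C @ dH / kT
    Cb = np.linalg.solve(A, C)           # (I + C dH/kT)^-1 C  (push-through)
    Cb = 0.5 * (Cb + Cb.T)
    cov_b = CovarianceMatrix(Cb, list(C_u.residues), C_u.temperature,
                             provenance="analytic")
    msf_u = C_u.msf()
    msf_b = cov_b.msf()
    with np.errstate(divide="ignore", invalid="ignore"):
        dmsf = (msf_b - msf_u) / msf_u ** 2
    fu, fb, z, sig, flag = z_profiles(msf_u, msf_b)
    return PerturbationResult(model, cov_b, msf_u, msf_b, dmsf,
                              fu, fb, z, sig, flag)


def apply_binding_hessian_route(C_u: CovarianceMatrix, model: BindingModel,
                                n_removed: int = 0,
                                rel_tol: float = 1e-10) -> CovarianceMatrix:
    """Alternative route: H_b = k_BT C_u^+ + delta_H; C_b = k_BT H_b^+.

    Matches ``apply_binding`` exactly for full-rank covariance; exposed for
    the algebraic cross-check.
    """
    H_u = hessian_from_covariance(C_u, n_removed=n_removed, rel_tol=rel_tol)
    dH = binding_increment(model, list(C_u.residues))
    H_b = Hessian(H_u.matrix + dH, list(C_u.residues), H_u.temperature,
                  H_u.retained_rank, H_u.removed_modes)
    return covariance_from_hessian(H_b, rel_tol=rel_tol)


# --------------------------------------------------------------------------
# Normalised fluctuation profiles and Z scores
# --------------------------------------------------------------------------

def modified_zscore(x: np.ndarray) -> np.ndarray:
    """Median/MAD outlier score with the conventional 0.6745 scaling."""
    x = np.asarray(x, float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x)
    return 0.6745 * (x - med) / mad


def _fnorm(msf: np.ndarray, outlier_threshold: float) -> np.ndarray:
    keep = np.abs(modified_zscore(msf)) <= outlier_threshold
    mu = msf[keep].mean()
    sd = msf[keep].std()
    if sd == 0:
        return np.full_like(msf, np.nan)
    return (msf - mu) / sd


def z_profiles(msf_a: np.ndarray, msf_b: np.ndarray,
               outlier_threshold: float = 3.5,
               significance: float = 1.0):
    """Normalised fluctuation profiles, their difference Z-score and mask.

    F_norm(i) = (MSF(i) - mu)/sigma with mu, sigma over non-outlier
    residues (modified Z-score > threshold excluded); Z_diff standardises
    the profile difference the same way.  Returns (F_a, F_b, Z_diff, mask,
    flag) where flag explains an undefined Z (flat difference).
    """
    msf_a = np.asarray(msf_a, float)
    msf_b = np.asarray(msf_b, float)
    if msf_a.shape != msf_b.shape:
        raise ValueError("profiles must share the residue range")
    fa = _fnorm(msf_a, outlier_threshold)
    fb = _fnorm(msf_b, outlier_threshold)
    flag = None
    if np.isnan(fa).all() or np.isnan(fb).all():
        flag = "flat MSF profile; F_norm undefined"
        return fa, fb, np.full_like(fa, np.nan), np.zeros(len(fa), bool), flag
    df = fb - fa
    keep = np.abs(modified_zscore(df)) <= outlier_threshold
    mu = df[keep].mean()
    sd = df[keep].std()
    if sd == 0:
        flag = "flat profile difference; Z_diff undefined"
        z = np.full_like(df, np.nan)
        return fa, fb, z, np.zeros(len(df), bool), flag
    z = (df - mu) / sd
    return fa, fb, z, np.abs(z) > significance, flag


# --------------------------------------------------------------------------
# Scanning and calibration
# --------------------------------------------------------------------------

def prs_scan(C_u: CovarianceMatrix, gamma: float = 5.0,
             core_range: tuple | None = None):
    """Z_diff(response residue | bound residue) for single-site binding.

    One grounded single-site model per residue of the core range (default:
    the helical core G29-M51 where present).  Rows are binding sites,
    columns responding residues.
    """
    residues = list(C_u.residues)
    if core_range is None:
        lo = max(29, residues[0])
        hi = min(51, residues[-1])
    else:
        lo, hi = core_range
    sites = [r for r in residues if lo <= r <= hi]
    if not sites:
        raise ValueError("core range contains no residues of the selection")
    Z = np.full((len(sites), len(residues)), np.nan)
    for k, site in enumerate(sites):
        res = apply_binding(C_u, BindingModel.single_site(site, gamma))
        Z[k] = res.z_diff
    return Z, sites, residues


@dataclass
class GammaCalibration:
    gammas: np.ndarray
    delta_msf: np.ndarray                # (n_gamma, n_residues)
    slopes: np.ndarray                   # finite differences d(dMSF)/d(gamma)
    linear_regime: np.ndarray            # per-residue flag (slope drift < 10%)


def calibrate_gamma(C_u: CovarianceMatrix, model: BindingModel,
                    gammas=tuple(range(1, 11))) -> GammaCalibration:
    """Relative MSF change vs binding spring constant (linear-response check).

    delta_MSF(i) = (MSF_b - MSF_u)/MSF_u^2 per residue and gamma; in the
    linear-response regime the ratio delta_MSF/gamma is constant.
    """
    gam = np.asarray(sorted(gammas), float)
    msf_u = C_u.msf()
    if (msf_u == 0).any():
        raise ValueError("MSF_u vanishes at a scanned residue")
    rows = []
    for g in gam:
        m = BindingModel(model.couplings, gamma=float(g), kappa=model.kappa,
                         n_sites=model.n_sites, grounded=model.grounded,
                         name=model.name)
        rows.append(apply_binding(C_u, m).delta_msf)
    dmsf = np.stack(rows)
    slopes = np.diff(dmsf, axis=0) / np.diff(gam)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        drift = np.abs(slopes[1] - slopes[0]) / np.abs(slopes[0])
    linear = drift < 0.10
    return GammaCalibration(gam, dmsf, slopes, linear)


# --------------------------------------------------------------------------
# Essential subspace and mode overlap
# --------------------------------------------------------------------------

@dataclass
class EssentialSubspace:
    vectors: np.ndarray                  # (3N, n) orthonormal columns
    eigenvalues: np.ndarray              # all eigenvalues, descending
    n_modes: int
    fraction: float
    residues: list


def essential_subspace(C: CovarianceMatrix, fraction: float = 0.85) -> EssentialSubspace:
    """Leading covariance eigenvectors covering the target MSF fraction."""
    w, v = np.linalg.eigh(C.matrix)
    w = w[::-1]
    v = v[:, ::-1]
    total = w.sum()
    if total <= 0:
        raise ValueError("zero covariance; essential subspace undefined")
    cum = np.cumsum(w) / total
    n = int(np.searchsorted(cum, fraction) + 1)
    return EssentialSubspace(v[:, :n], w, n, fraction, list(C.residues))


def overlap(mode_vector: np.ndarray, sub: EssentialSubspace):
    """Squared projection of a unit mode onto the essential subspace.

    Returns ``(cumulative, per_mode_average)``: the cumulative
    sum_i (FM.v_i)^2 in [0, 1] is the primary statistic; the average
    divides by the subspace dimension n.
    """
    fm = np.asarray(mode_vector, float)
    if fm.shape[0] != sub.vectors.shape[0]:
        raise ValueError("mode and subspace dimensions differ")
    nv = np.linalg.norm(fm)
    if nv == 0:
        raise ValueError("zero mode vector")
    fm = fm / nv
    proj = sub.vectors.T @ fm
    cum = float((proj ** 2).sum())
    return cum, cum / sub.n_modes


def mode_overlap(fm, sub: EssentialSubspace):
    """Overlap of a FunctionalMode (backbone atoms) with a Cα subspace."""
    from .fma import FunctionalMode
    if isinstance(fm, FunctionalMode):
        vec = fm.ca_subvector()
    else:
        vec = fm
    return overlap(vec, sub)
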