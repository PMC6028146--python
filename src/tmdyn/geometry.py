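"""Helix-segment axes, bend/swivel orientation and hinge decomposition.

Orientation convention
----------------------
The orientation frame follows the S-state convention used throughout the
package: the axis of the N-terminal reference segment (default A30-L34) is
aligned with +z pointing N->C, the frame is rotated about z until the Cα of
the azimuth reference residue (default G33) lies on the +x axis, and
azimuths are measured *clockwise* when viewed from the C-terminal (+z) end.
On an exact right-handed helix with 3.6 residues per turn this places
G29/G33/G37/G38 at +40/0/-40/-140 degrees -- the glycine ladder that pins
down handedness and sign.

Segment axes are computed differential-geometrically: the cross product of
successive Cα bisectors is the local helix-axis direction (exact on an
ideal helix, unlike a principal-component fit which is strongly biased for
5-residue windows); the axis anchor point comes from a least-squares circle
fit in the normal plane.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble import Conformation, Ensemble
from .residues import ResidueMap, Selection


@dataclass(frozen=True)
class SegmentSpec:
    """Residue range (C99 numbering, inclusive) defining a helix segment."""

    first: int
    last: int

    def __post_init__(self):
        if self.last - self.first + 1 < 4:
            raise ValueError("segment needs >=4 residues for an axis fit")

    def ca(self, conf: Conformation) -> np.ndarray:
        return conf.ca((self.first, self.last))


TM_N = SegmentSpec(30, 34)     # A30-L34
TM_C = SegmentSpec(47, 51)     # I47-M51, carries the epsilon-sites
DEFAULT_AZIMUTH_REF = 33       # G33


# --------------------------------------------------------------------------
# Axis fitting
# --------------------------------------------------------------------------

def segment_axis_points(ca: np.ndarray):
    """Local axis directions from successive-bisector cross products."""
    ca = np.asarray(ca, float)
    if len(ca) < 4:
        raise ValueError("need >=4 Calpha positions")
    axes = []
    for i in range(1, len(ca) - 2):
        b1 = (ca[i - 1] - ca[i]) + (ca[i + 1] - ca[i])
        b2 = (ca[i] - ca[i + 1]) + (ca[i + 2] - ca[i + 1])
        n1, n2 = np.linalg.norm(b1), np.linalg.norm(b2)
        if n1 < 1e-10 or n2 < 1e-10:
            raise ValueError("degenerate (collinear) backbone geometry")
        a = np.cross(b1 / n1, b2 / n2)
        na = np.linalg.norm(a)
        if na < 1e-10:
            raise ValueError("degenerate (collinear) backbone geometry")
        axes.append(a / na)
    return np.asarray(axes)


def _circle_center(p2: np.ndarray) -> np.ndarray:
    # Kasa algebraic circle fit
    A = np.c_[2.0 * p2, np.ones(len(p2))]
    b = (p2 ** 2).sum(1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:2]


def fit_axis(ca: np.ndarray):
    """Helix axis of a Cα segment.

    Returns ``(direction, center)``: a unit vector with N->C sign and a
    point on the axis.
    """
    axes = segment_axis_points(ca)
    d = axes.mean(0)
    nd = np.linalg.norm(d)
    if nd < 1e-10:
        raise ValueError("axis direction is degenerate")
    d = d / nd
    if np.dot(ca[-1] - ca[0], d) < 0:
        d = -d
    # anchor: circle fit in the plane perpendicular to d
    tmp = np.eye(3)[int(np.argmin(np.abs(d)))]
    u = np.cross(d, tmp)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    c2 = _circle_center(np.c_[ca @ u, ca @ v])
    center = c2[0] * u + c2[1] * v + float((ca @ d).mean()) * d
    return d, center


def fit_segment_axis(conf: Conformation, segment: SegmentSpec):
    """Axis (unit direction, N->C sign) and anchor point of a helix segment."""
    return fit_axis(segment.ca(conf))


def orientation_frame(conf: Conformation, segN: SegmentSpec = TM_N,
                      azimuth_ref: int = DEFAULT_AZIMUTH_REF):
    """Orthonormal frame (x, y, z, origin) of the orientation convention.

    z is the segN axis (N->C); x points at the azimuth-reference Cα;
    y = x × z so that atan2(·y, ·x) increases clockwise viewed from +z.
    """
    z, c = fit_segment_axis(conf, segN)
    ref = conf.ca((azimuth_ref, azimuth_ref))[0]
    r = ref - c
    x = r - np.dot(r, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        raise ValueError("azimuth reference residue lies on the segment axis")
    x /= nx
    y = np.cross(x, z)
    return x, y, z, c


def residue_azimuth(conf: Conformation, segN: SegmentSpec = TM_N,
                    azimuth_ref: int = DEFAULT_AZIMUTH_REF,
                    residue: int | None = None) -> float:
    """Azimuth (deg, clockwise from +x viewed from +z) of a residue's Cα."""
    if residue is None:
        raise ValueError("residue (C99 number) is required")
    x, y, z, c = orientation_frame(conf, segN, azimuth_ref)
    p = conf.ca((residue, residue))[0] - c
    px, py = np.dot(p, x), np.dot(p, y)
    if np.hypot(px, py) < 1e-8:
        raise ValueError("residue lies on the z-axis; azimuth undefined")
    return float(np.degrees(np.arctan2(py, px)))


# --------------------------------------------------------------------------
# Bend / swivel
# --------------------------------------------------------------------------

@dataclass
class OrientationSeries:
    """Per-frame bend angle theta [0,180) and swivel angle Phi (-180,180].

    Phi is NaN wherever theta is below the degeneracy threshold.
    """

    theta: np.ndarray
    phi: np.ndarray
    degeneracy_threshold: float = 2.0

    def as_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"frame": np.arange(len(self.theta)),
                             "theta_deg": self.theta, "phi_deg": self.phi})


def bend_swivel(ens: Ensemble, segN: SegmentSpec = TM_N,
                segC: SegmentSpec = TM_C,
                azimuth_ref: int = DEFAULT_AZIMUTH_REF,
                degeneracy_threshold: float = 2.0) -> OrientationSeries:
    """Bend/swivel orientation of segC relative to segN, frame by frame."""
    thetas = np.empty(ens.n_frames)
    phis = np.empty(ens.n_frames)
    for f in range(ens.n_frames):
        conf = ens.frame(f)
        x, y, z, _ = orientation_frame(conf, segN, azimuth_ref)
        aC, _ = fit_segment_axis(conf, segC)
        ct = float(np.clip(np.dot(aC, z), -1.0, 1.0))
        theta = np.degrees(np.arccos(ct))
        px, py = np.dot(aC, x), np.dot(aC, y)
        phi = np.degrees(np.arctan2(py, px)) if theta >= degeneracy_threshold else np.nan
        thetas[f], phis[f] = theta, phi
    return OrientationSeries(thetas, phis, degeneracy_threshold)


@dataclass
class OrientationStatistics:
    phi_bin_edges: np.ndarray
    phi_populations: np.ndarray          # normalised fractions per 45 deg bin
    theta_class_edges: tuple
    theta_class_populations: np.ndarray  # small / intermediate / large
    polar_hist: np.ndarray               # (n_theta, n_phi) normalised to max
    polar_theta_edges: np.ndarray
    polar_phi_edges: np.ndarray


def orientation_statistics(samples: OrientationSeries, phi_bin: float = 45.0,
                           theta_classes=(20.0, 40.0),
                           polar_bin: float = 2.0) -> OrientationStatistics:
    """Swivel-bin populations, bend-angle classes and the 2D polar histogram.

    Phi bins are centred on 0 deg (edges at ±phi_bin/2, ...), classes are
    left-closed/right-open and the 2D histogram is normalised to its highest
    bin.
    """
    theta = samples.theta
    phi = samples.phi
    ok = np.isfinite(phi)
    if not ok.any():
        raise ValueError("all swivel angles undefined; nothing to bin")
    nbin = int(round(360.0 / phi_bin))
    edges = -180.0 + phi_bin / 2.0 + phi_bin * np.arange(nbin + 1)
    shifted = (phi[ok] - edges[0]) % 360.0
    counts = np.histogram(shifted, bins=np.arange(nbin + 1) * phi_bin)[0]
    phi_pop = counts / counts.sum()
    lo, hi = theta_classes
    tc = np.array([np.mean(theta < lo),
                   np.mean((theta >= lo) & (theta < hi)),
                   np.mean(theta >= hi)])
    t_edges = np.arange(0.0, 180.0 + polar_bin, polar_bin)
    p_edges = np.arange(-180.0, 180.0 + polar_bin, polar_bin)
    H = np.histogram2d(theta[ok], phi[ok], bins=[t_edges, p_edges])[0]
    if H.max() > 0:
        H = H / H.max()
    return OrientationStatistics(edges, phi_pop, theta_classes, tc,
                                 H, t_edges, p_edges)


# --------------------------------------------------------------------------
# Screw-axis hinge decomposition (DynDom-style surrogate)
# --------------------------------------------------------------------------

@dataclass
class ScrewDecomposition:
    domains: list                 # [(first, last)] in C99 numbering
    hinges: list                  # list (per inter-domain gap) of residue lists
    pair_angles: list             # rotation angle (deg) per adjacent pair
    pair_axes: list               # screw axis unit vector per pair
    pair_closure: list            # %closure per pair
    pair_labels: list             # 'B' or 'T' per pair
    motion_type: str              # none | B | T | BB | BT | TB | TT | M


def _window_rotations(ca_ref: np.ndarray, ca: np.ndarray, window: int):
    from .ensemble import kabsch
    rots = []
    for s in range(len(ca) - window + 1):
        R, _ = kabsch(ca_ref[s:s + window], ca[s:s + window])
        rots.append(Rotation.from_matrix(R))
    return rots


def _relative_angle(r1: Rotation, r2: Rotation) -> float:
    return float(np.degrees((r1.inv() * r2).magnitude()))


def screw_decomposition(conf: Conformation, reference: Conformation,
                        window: int = 5, min_domain: int = 4,
                        cluster_angle_tol: float = 15.0,
                        min_motion_angle: float = 5.0,
                        selection: Selection | None = None) -> ScrewDecomposition:
    """Quasi-rigid domains, hinges and bend/twist labels for one frame.

    Sliding-window rotations onto the reference are agglomerated along the
    sequence: a window joins the running cluster while its rotation is within
    ``cluster_angle_tol`` of the cluster mean.  Residues whose covering
    windows disagree become hinge residues.  %closure = 100 sin^2(angle
    between the inter-domain screw axis and the reference helix axis); >50
    labels bending, otherwise twisting.
    """
    sel = selection or Selection(("CA",), None)
    idx_c = sel.resolve(conf.topology, conf.residue_map)
    idx_r = sel.resolve(reference.topology, reference.residue_map)
    ca = conf.xyz[idx_c]
    ca_ref = reference.xyz[idx_r]
    if ca.shape != ca_ref.shape:
        raise ValueError("conformation/reference topology mismatch")
    n = len(ca)
    resnums = [conf.residue_map.number_of(int(conf.topology.atom_resid[i]))
               for i in idx_c]
    helix_axis, _ = fit_axis(ca_ref)

    rots = _window_rotations(ca_ref, ca, window)
    # sequence-ordered agglomeration against the running cluster mean
    clusters = []          # list of window-index lists
    current = [0]
    for w in range(1, len(rots)):
        mean = Rotation.mean(Rotation.concatenate([rots[i] for i in current]))
        if _relative_angle(mean, rots[w]) < cluster_angle_tol:
            current.append(w)
        else:
            clusters.append(current)
            current = [w]
    clusters.append(current)

    # residue -> set of clusters covering it
    win_cluster = {}
    for ci, ws in enumerate(clusters):
        for w in ws:
            win_cluster[w] = ci
    cover = [set() for _ in range(n)]
    for w in range(len(rots)):
        for r in range(w, w + window):
            cover[r].add(win_cluster[w])

    # domains: maximal runs of residues covered by exactly one cluster
    domains = []           # (start, end, cluster) residue positions, inclusive
    start = None
    for r in range(n + 1):
        uni = len(cover[r]) == 1 if r < n else False
        if uni and start is None:
            start = r
        elif start is not None and (not uni or next(iter(cover[r])) != next(iter(cover[start]))):
            domains.append((start, r - 1, next(iter(cover[start]))))
            start = r if uni else None
    domains = [d for d in domains if d[1] - d[0] + 1 >= min_domain]
    if not domains:
        raise ValueError("no quasi-rigid domain found (all windows disordered)")

    dom_rot = []
    for (s, e, cl) in domains:
        # windows fully inside the domain carry its pure rotation; windows
        # straddling a hinge would dilute the inter-domain angle
        ws = [w for w in clusters[cl] if w >= s and w + window - 1 <= e]
        if not ws:
            ws = list(clusters[cl])
        dom_rot.append(Rotation.mean(Rotation.concatenate([rots[w] for w in ws])))

    hinges, angles, axes, closures, labels = [], [], [], [], []
    for k in range(len(domains) - 1):
        gap = list(range(domains[k][1] + 1, domains[k + 1][0]))
        hinges.append([resnums[r] for r in gap])
        rel = dom_rot[k].inv() * dom_rot[k + 1]
        ang = float(np.degrees(rel.magnitude()))
        rv = rel.as_rotvec()
        axis = rv / np.linalg.norm(rv) if np.linalg.norm(rv) > 1e-12 else helix_axis
        cosb = float(np.clip(abs(np.dot(axis, helix_axis)), 0.0, 1.0))
        closure = 100.0 * (1.0 - cosb ** 2)
        angles.append(ang)
        axes.append(axis)
        closures.append(closure)
        labels.append("B" if closure > 50.0 else "T")

    moving = [k for k in range(len(angles)) if angles[k] >= min_motion_angle]
    if not moving:
        motion = "none"
    elif len(moving) == 1:
        motion = labels[moving[0]]
    elif len(moving) == 2:
        motion = labels[moving[0]] + labels[moving[1]]
    else:
        motion = "M"

    dom_ranges = [(resnums[s], resnums[e]) for (s, e, _) in domains]
    return ScrewDecomposition(dom_ranges, hinges, angles, axes, closures,
                              labels, motion)


@dataclass
class HingeStatistics:
    motion_fractions: dict               # class -> fraction of frames
    single_hinge_probability: dict       # residue -> probability
    double_hinge_probability: dict
    n_frames: int


def hinge_statistics(ens: Ensemble, reference: Conformation,
                     **screw_kwargs) -> HingeStatistics:
    """Aggregate screw decompositions over an ensemble.

    Motion classes: none, B, T, BB, BT, TB, TT, M.  Per-residue hinge
    frequencies are collected separately for single- and double-hinge frames.
    """
    counts = {k: 0 for k in ("none", "B", "T", "BB", "BT", "TB", "TT", "M")}
    single, double = {}, {}
    for f in range(ens.n_frames):
        try:
            dec = screw_decomposition(ens.frame(f), reference, **screw_kwargs)
        except ValueError:
            counts["none"] += 1
            continue
        counts[dec.motion_type] = counts.get(dec.motion_type, 0) + 1
        tgt = single if dec.motion_type in ("B", "T") else (
            double if len(dec.motion_type) == 2 else None)
        if tgt is not None:
            for gap in dec.hinges:
                for r in gap:
                    tgt[r] = tgt.get(r, 0) + 1
        # frames classified none contribute no hinge residues
    nf = ens.n_frames
    n_single = counts["B"] + counts["T"]
    n_double = sum(counts[k] for k in ("BB", "BT", "TB", "TT"))
    return HingeStatistics(
        {k: v / nf for k, v in counts.items()},
        {r: v / n_single for r, v in single.items()} if n_single else {},
        {r: v / n_double for r, v in double.items()} if n_double else {},
        nf)


def pick_reference(ens: Ensemble, selection: Selection | None = None) -> Conformation:
    """Frame with the lowest RMSD from the iterative mean structure."""
    from .ensemble import iterative_mean_structure, rmsd_to
    sel = selection or Selection(("CA",), None)
    mean, _ = iterative_mean_structure(ens, sel)
    rmsds = [rmsd_to(ens.frame(f), mean, sel) for f in range(ens.n_frames)]
    return ens.frame(int(np.argmin(rmsds)))
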