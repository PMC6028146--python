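"""Per-residue metrics: H-bonds, packing, hydration, dihedrals, rise, RMSF."""
import numpy as np
import pytest

from tmdyn import (
    Conformation,
    Ensemble,
    HBondCriterion,
    HelixParams,
    HingeSpec,
    ResidueMap,
    Selection,
    arc_length,
    backbone_dihedrals,
    build_ideal_helix,
    convergence_diagnostics,
    generate_hinge_ensemble,
    generate_solvent_cloud,
    hbond_occupancy,
    packing_score,
    parametric_ca_helix,
    rise_per_residue,
    rmsf,
    solvent_shell_fractions,
    water_coordination,
)
from tmdyn.ensemble import Topology
from tmdyn.local import _first_zero_crossing

from conftest import WT_SEQ


def single_frame_ens(conf):
    return Ensemble(conf.topology, conf.xyz[None].copy(), conf.residue_map)


class TestHBondOccupancy:
    def test_rigid_ideal_helix_fully_closed(self, rigid_ensemble):
        occ = hbond_occupancy(rigid_ensemble)
        interior = np.isfinite(occ.alpha)      # carbonyls with an i+4 partner
        assert interior.sum() > 20
        assert np.all(occ.combined[interior] == 1.0)

    def test_combined_bounds(self, noisy_ensemble):
        occ = hbond_occupancy(noisy_ensemble)
        d = np.isfinite(occ.combined) & np.isfinite(occ.alpha) & np.isfinite(occ.three10)
        assert np.all(occ.combined[d] >= np.maximum(occ.alpha[d], occ.three10[d]) - 1e-12)
        assert np.all(occ.combined[d] <= occ.alpha[d] + occ.three10[d] + 1e-12)

    def test_boundary_strictly_2p6(self, wt_helix):
        """H displaced to 2.7 A from O opens the bond; at 2.6 it stays closed."""
        top = wt_helix.topology
        r = wt_helix.residue_map.index_of(33)
        i_o = top.atom_index(r, "O")
        i_h = top.atom_index(r + 4, "H")
        for dist, expect in ((2.7, False), (2.6 - 1e-9, True)):
            xyz = wt_helix.xyz.copy()
            direction = xyz[i_h] - xyz[i_o]
            direction /= np.linalg.norm(direction)
            xyz[i_h] = xyz[i_o] + dist * direction
            ens = Ensemble(top, xyz[None], wt_helix.residue_map)
            occ = hbond_occupancy(ens)
            assert bool(occ.closed[0, r, 0]) is expect

    def test_rigid_motion_invariance(self, wt_helix):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("xyz", [40, -30, 100], degrees=True).as_matrix()
        moved = Conformation(wt_helix.topology, wt_helix.xyz @ R.T + 7.0,
                             wt_helix.residue_map)
        occ_a = hbond_occupancy(single_frame_ens(wt_helix))
        occ_b = hbond_occupancy(single_frame_ens(moved))
        assert np.array_equal(occ_a.closed, occ_b.closed)

    def test_hinge_bend_opens_convex_side_locally(self, wt_helix):
        spec = HingeSpec(hinge=37, bend_mean=40.0, bend_sd=0.0,
                         azimuth_mean=-40.0)
        ens = generate_hinge_ensemble(wt_helix, spec, 3, seed=2)
        occ = hbond_occupancy(ens)
        dip = [n for n, c, a in zip(occ.c99_numbers, occ.combined, occ.alpha)
               if n is not None and np.isfinite(a) and c < 0.95]
        assert dip, "a 40-degree bend must open at least one bond"
        assert all(33 <= n <= 37 for n in dip)


class TestPackingScore:
    def test_single_atom_closed_form(self):
        top = Topology(("O", "CA"), np.array([0, 1]), ("O", "C"))
        rm = ResidueMap.linear("GG")
        conf = Conformation(top, np.array([[0.0, 0, 0], [2.0, 0, 0]]), rm)
        prof = packing_score(single_frame_ens(conf))
        assert prof.values[0] == pytest.approx(100.0 * 2.0 ** -6, abs=1e-12)
        conf4 = Conformation(top, np.array([[0.0, 0, 0], [4.0, 0, 0]]), rm)
        prof4 = packing_score(single_frame_ens(conf4))
        assert prof.values[0] / prof4.values[0] == pytest.approx(64.0, rel=1e-12)

    def test_matches_bruteforce_double_loop(self, wt_helix):
        prof = packing_score(single_frame_ens(wt_helix))
        top = wt_helix.topology
        for r in range(top.n_residues):
            i_o = top.atom_index(r, "O")
            if i_o is None:
                continue
            s = 0.0
            for j in range(top.n_atoms):
                if int(top.atom_resid[j]) == r:
                    continue
                s += np.linalg.norm(wt_helix.xyz[j] - wt_helix.xyz[i_o]) ** -6
            assert prof.values[r] == pytest.approx(100.0 * s, abs=1e-9)

    def test_clashing_frame_rejected(self, wt_helix):
        xyz = np.repeat(wt_helix.xyz[None], 2, axis=0)
        top = wt_helix.topology
        i_o = top.atom_index(0, "O")
        j = top.atom_index(1, "CA")
        xyz[1, j] = xyz[1, i_o] + 0.1     # cross-residue overlap, frame 1 only
        ens = Ensemble(wt_helix.topology, xyz, wt_helix.residue_map)
        prof = packing_score(ens)
        assert prof.rejected_frames == [1]


class TestWaterCoordination:
    def test_solvent_free_is_error_not_zero(self, rigid_ensemble):
        with pytest.raises(ValueError):
            water_coordination(rigid_ensemble)

    def test_single_placed_water(self, wt_helix):
        from tmdyn.ensemble import Solvent
        r = wt_helix.residue_map.index_of(40)
        o = wt_helix.xyz[wt_helix.topology.atom_index(r, "O")]
        h1 = o + np.array([2.5, 0.0, 0.0])
        solv = Solvent(np.array([[o + [3.3, 0, 0], h1, o + [3.0, 1.0, 0]]]),
                       ("OW", "HW1", "HW2"), np.array([0, 0, 0]), ("HOH",))
        ens = Ensemble(wt_helix.topology, wt_helix.xyz[None],
                       wt_helix.residue_map, solvent=solv)
        prof = water_coordination(ens)
        assert prof.values[r] == 1.0
        others = np.delete(prof.values, r)
        assert np.nansum(others) == 0.0

    def test_matches_bruteforce_allpairs(self, wt_helix):
        ens = generate_solvent_cloud(wt_helix, n_water=500, n_tfe=0,
                                     box=70.0, seed=3)
        prof = water_coordination(ens)
        solv = ens.solvent
        top = wt_helix.topology
        for r in range(top.n_residues):
            i_o = top.atom_index(r, "O")
            if i_o is None:
                continue
            count = 0
            for s in range(len(solv.site_names)):
                if not solv.site_names[s].startswith("H"):
                    continue
                if solv.species[solv.mol_index[s]] != "HOH":
                    continue
                if np.linalg.norm(solv.xyz[0, s] - wt_helix.xyz[i_o]) <= 2.6:
                    count += 1
            assert prof.values[r] == pytest.approx(count, abs=1e-9)


class TestDihedrals:
    def test_builder_roundtrip(self, rigid_ensemble):
        phi, psi = backbone_dihedrals(rigid_ensemble)
        d = np.isfinite(phi.values)
        assert np.allclose(phi.values[d], -57.0, atol=1e-6)
        d = np.isfinite(psi.values)
        assert np.allclose(psi.values[d], -47.0, atol=1e-6)

    def test_circular_mean_near_180(self):
        """Frames at psi=+179 and -179 must average to +/-180, not 0."""
        a = build_ideal_helix("GAILV", HelixParams(phi=-57, psi=179.0))
        b = build_ideal_helix("GAILV", HelixParams(phi=-57, psi=-179.0))
        ens = Ensemble(a.topology, np.stack([a.xyz, b.xyz]), a.residue_map)
        _, psi = backbone_dihedrals(ens)
        d = np.isfinite(psi.values)
        assert np.all(np.abs(np.abs(psi.values[d]) - 180.0) < 1e-6)

    def test_alpha_vs_three_ten_psi_offset(self, rigid_ensemble, wt_helix):
        from tmdyn import THREE_TEN
        c310 = build_ideal_helix(WT_SEQ, THREE_TEN)
        _, psi_a = backbone_dihedrals(rigid_ensemble)
        _, psi_t = backbone_dihedrals(single_frame_ens(c310))
        d = np.isfinite(psi_a.values) & np.isfinite(psi_t.values)
        assert np.allclose(psi_t.values[d] - psi_a.values[d], 21.0, atol=1e-6)


class TestRiseAndArc:
    def test_parametric_roundtrip(self):
        conf = parametric_ca_helix("G" * 20, rise=1.5)
        prof = rise_per_residue(conf)
        d = np.isfinite(prof.values)
        assert d.sum() == 17
        assert np.allclose(prof.values[d], 1.5, atol=1e-6)

    def test_straight_line_flagged_not_crash(self):
        top = Topology.calpha(8)
        conf = Conformation(top, np.c_[np.zeros(8), np.zeros(8),
                                       np.arange(8.0) * 1.5],
                            ResidueMap.linear("G" * 8))
        prof = rise_per_residue(conf)
        assert not np.isfinite(prof.values).any()

    def test_rigid_motion_invariance(self, wt_helix):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("zyx", [17, 120, -63], degrees=True).as_matrix()
        moved = Conformation(wt_helix.topology, wt_helix.xyz @ R.T - 12.3,
                             wt_helix.residue_map)
        a = rise_per_residue(wt_helix).values
        b = rise_per_residue(moved).values
        d = np.isfinite(a)
        assert np.allclose(a[d], b[d], atol=1e-9)

    def test_arc_additivity_and_zero(self, wt_param_helix):
        assert arc_length(wt_param_helix, 33, 33) == 0.0
        ab = arc_length(wt_param_helix, 33, 40)
        bc = arc_length(wt_param_helix, 40, 50)
        ac = arc_length(wt_param_helix, 33, 50)
        assert ab + bc == pytest.approx(ac, abs=1e-12)

    def test_arc_touching_terminals_rejected(self, wt_param_helix):
        last = wt_param_helix.residue_map.mapped_numbers[-1]
        with pytest.raises(ValueError):
            arc_length(wt_param_helix, 33, last)


class TestRmsf:
    def test_identical_frames_zero(self, rigid_ensemble):
        prof = rmsf(rigid_ensemble)
        assert np.nanmax(prof.values) < 1e-9

    def test_isotropic_gaussian_closed_form(self):
        """Per-atom isotropic variance sigma^2 I3 gives RMSF = sigma*sqrt(3)
        up to the ~6/(3N) fluctuation absorbed by superposition."""
        from tmdyn import HarmonicModel, generate_harmonic_ensemble
        n = 60
        rng = np.random.default_rng(1)
        conf = Conformation(Topology.calpha(n), rng.uniform(0, 50, (n, 3)),
                            ResidueMap.linear("G" * n))
        sigma = 0.7
        T = 1.0 / 1.9872041e-3
        H = np.eye(3 * n) / sigma ** 2          # kBT/lambda = sigma^2
        ens = generate_harmonic_ensemble(HarmonicModel(conf, H, temperature=T),
                                         20000, seed=3)
        prof = rmsf(ens)
        assert np.nanmean(prof.values) == pytest.approx(sigma * np.sqrt(3),
                                                        rel=0.03)

    def test_hinge_lever_arm_monotone(self, wt_helix):
        """Superposed on the static N-terminal segment, Calpha fluctuation
        grows with the lever arm from the hinge."""
        from tmdyn import iterative_mean_structure, superpose
        spec = HingeSpec(hinge=37, bend_mean=0.0, bend_sd=12.0)
        ens = generate_hinge_ensemble(wt_helix, spec, 300, seed=6)
        from tmdyn.geometry import orientation_frame
        sel = Selection(("CA",), (29, 36))
        mean, _ = iterative_mean_structure(ens, sel)
        sup = superpose(ens, mean, sel)
        x0, y0, z, _ = orientation_frame(wt_helix)
        d = np.cos(np.deg2rad(-40)) * x0 + np.sin(np.deg2rad(-40)) * y0
        u = np.cross(z, d)
        u /= np.linalg.norm(u)
        piv = wt_helix.xyz[wt_helix.topology.atom_index(
            wt_helix.residue_map.index_of(37), "CA")]
        ratios = []
        for n in range(39, 53):
            i = sup.topology.atom_index(sup.residue_map.index_of(n), "CA")
            r = wt_helix.xyz[i] - piv
            dist_axis = np.linalg.norm(r - np.dot(r, u) * u)
            fl = sup.xyz[:, i] - sup.xyz[:, i].mean(0)
            ratios.append(np.sqrt((fl ** 2).sum(1).mean()) / dist_axis)
        # fluctuation proportional to the lever arm (distance from the
        # rotation axis), with slope = the sampled bend sd in radians
        assert np.ptp(ratios) / np.mean(ratios) < 0.01
        assert np.mean(ratios) == pytest.approx(np.deg2rad(12.0), rel=0.15)


class TestSolventShells:
    def test_equal_densities_null(self, wt_helix):
        ens = generate_solvent_cloud(wt_helix, n_water=3000, n_tfe=3000,
                                     box=70.0, seed=12)
        profiles = solvent_shell_fractions(ens)
        for prof in profiles:
            assert abs(np.nanmean(prof.values)) < 0.1

    def test_water_only_vs_equimolar_reference(self, wt_helix):
        ens = generate_solvent_cloud(wt_helix, n_water=800, n_tfe=0,
                                     box=70.0, seed=1)
        profiles = solvent_shell_fractions(ens, bulk_reference=0.5)
        for prof in profiles:
            d = np.isfinite(prof.values)
            assert np.allclose(prof.values[d], 0.5)

    def test_constructed_local_enrichment(self, wt_helix):
        from tmdyn.ensemble import Solvent
        rng = np.random.default_rng(4)
        r = wt_helix.residue_map.index_of(40)
        ca = wt_helix.xyz[wt_helix.topology.atom_index(r, "CA")]
        waters = ca + rng.normal(0, 1.0, (40, 3))
        tfes = wt_helix.xyz.mean(0) + rng.uniform(-35, 35, (400, 3))
        sites, names, mol, species = [], [], [], []
        for k, w in enumerate(waters):
            sites.append(w)
            names.append("OW")
            mol.append(k)
            species.append("HOH")
        for k, tpos in enumerate(tfes):
            sites.append(tpos)
            names.append("CT")
            mol.append(len(waters) + k)
            species.append("TFE")
        solv = Solvent(np.array(sites)[None], tuple(names), np.array(mol),
                       tuple(species))
        ens = Ensemble(wt_helix.topology, wt_helix.xyz[None],
                       wt_helix.residue_map, solvent=solv)
        shellA = solvent_shell_fractions(ens)[0]
        bulk = 40 / 440
        assert shellA.values[r] > 0.3
        far = [v for n, v in zip(shellA.c99_numbers, shellA.values)
               if n is not None and abs(n - 40) > 6 and np.isfinite(v)]
        assert np.nanmean(far) < 0.0      # depleted relative to bulk


class TestConvergence:
    def test_identical_frames_zero_window_rmsd(self, wt_helix):
        ens = Ensemble(wt_helix.topology,
                       np.repeat(wt_helix.xyz[None], 20, axis=0),
                       wt_helix.residue_map, frame_spacing_ns=0.05)
        rep = convergence_diagnostics(ens)
        assert np.all(rep.window_rmsd < 1e-9)

    def test_white_noise_correlation_time_about_one_frame(self, noisy_ensemble):
        """Uncorrelated coordinate noise decorrelates within ~1 frame."""
        rep = convergence_diagnostics(noisy_ensemble)
        frames = rep.hbond_corr_times / noisy_ensemble.frame_spacing_ns
        assert np.median(frames) <= 1.0
        assert frames.mean() <= 3.0

    def test_ar1_first_zero_matches_simulated_expectation(self):
        """Estimator vs an independent naive implementation on AR(1) series."""
        rho, n = 0.9, 10000
        rng = np.random.default_rng(77)

        def naive_first_zero(x):
            x = x - x.mean()
            ac = [np.dot(x[:len(x) - k], x[k:]) for k in range(len(x) // 4)]
            for k, v in enumerate(ac):
                if v <= 0:
                    return k
            return len(ac)

        def ar1(seed):
            r = np.random.default_rng(seed)
            x = np.empty(n)
            x[0] = r.standard_normal()
            eps = r.standard_normal(n)
            for i in range(1, n):
                x[i] = rho * x[i - 1] + eps[i]
            return x

        expectation = np.mean([naive_first_zero(ar1(s)) for s in range(20)])
        est = _first_zero_crossing(ar1(999))
        assert abs(est - expectation) / expectation < 0.25
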