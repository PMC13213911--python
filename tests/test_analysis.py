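"""Analysis stack: Kabsch superposition, cross-RMSD, interaction-energy
decomposition, contact fingerprints and replica ranking — each checked
against an independent brute-force oracle."""

import numpy as np
import pytest

from sumdkit import (
    Component,
    ForceFieldTerms,
    Frame,
    ReplicaMetrics,
    Trajectory,
    build_selection,
    contact_table,
    cross_rmsd,
    interaction_energy,
    interaction_energy_series,
    per_residue_profile,
    rank_replicas,
    replica_metrics,
    superpose,
)
from sumdkit.units import COULOMB_K

from conftest import make_beads, random_coords


def rotation_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def quaternion_grid_rmsd(mobile, reference, n_coarse=4000, n_refine=3, seed=0):
    """Brute-force minimum RMSD over rotations: random-quaternion search
    with shrinking local refinement.  Independent of the Kabsch path."""
    rng = np.random.default_rng(seed)
    p = mobile - mobile.mean(0)
    q = reference - reference.mean(0)

    def rmsd_of_quat(quats):
        w, x, y, z = quats.T
        R = np.empty((len(quats), 3, 3))
        R[:, 0, 0] = 1 - 2 * (y * y + z * z)
        R[:, 0, 1] = 2 * (x * y - z * w)
        R[:, 0, 2] = 2 * (x * z + y * w)
        R[:, 1, 0] = 2 * (x * y + z * w)
        R[:, 1, 1] = 1 - 2 * (x * x + z * z)
        R[:, 1, 2] = 2 * (y * z - x * w)
        R[:, 2, 0] = 2 * (x * z - y * w)
        R[:, 2, 1] = 2 * (y * z + x * w)
        R[:, 2, 2] = 1 - 2 * (x * x + y * y)
        moved = np.einsum("kij,nj->kni", R, p)
        return np.sqrt(((moved - q) ** 2).sum(-1).mean(-1))

    best_q = np.array([1.0, 0, 0, 0])
    best = rmsd_of_quat(best_q[None])[0]
    sigma = 1.0
    for stage in range(n_refine + 1):
        if stage == 0:
            quats = rng.standard_normal((n_coarse, 4))
        else:
            quats = best_q + sigma * rng.standard_normal((n_coarse, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        vals = rmsd_of_quat(quats)
        k = int(np.argmin(vals))
        if vals[k] < best:
            best, best_q = vals[k], quats[k]
        sigma *= 0.1
    return best


class TestSuperpose:
    def test_identical_sets(self, rng):
        x = random_coords(rng, 6)
        res = superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)
        assert np.allclose(res.translation, 0.0, atol=1e-8)

    def test_exact_rigid_motion_recovered(self, rng):
        x = random_coords(rng, 8)
        ref = x @ rotation_z(np.pi / 2).T + np.array([1.0, 2.0, 3.0])
        res = superpose(x, ref)
        assert res.rmsd < 1e-8
        # rotation is proper and orthonormal
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_matches_quaternion_grid_oracle(self, rng):
        for trial in range(3):
            a = random_coords(rng, 6)
            b = random_coords(rng, 6)
            kab = superpose(a, b).rmsd
            brute = quaternion_grid_rmsd(a, b, seed=trial)
            assert kab <= brute + 1e-9  # Kabsch is optimal
            assert brute == pytest.approx(kab, abs=1e-3)

    def test_matches_mdanalysis_rmsd(self, rng):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        a = random_coords(rng, 10)
        b = random_coords(rng, 10)
        assert superpose(a, b).rmsd == pytest.approx(
            mda_rmsd(a, b, center=True, superposition=True), abs=1e-6
        )

    def test_never_worse_than_unsuperposed(self, rng):
        for _ in range(10):
            a = random_coords(rng, 7)
            b = random_coords(rng, 7)
            raw = np.sqrt(((a - b) ** 2).sum(1).mean())
            assert superpose(a, b).rmsd <= raw + 1e-12

    def test_degenerate_points_error(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            superpose(line, line)


class TestCrossRmsd:
    def _setup(self, rng):
        system = make_beads(10)
        ref = Frame(coordinates=random_coords(rng, 10))
        align = build_selection(system, "resid 1-6")
        measure = build_selection(system, "resid 7-10")
        return system, ref, align, measure

    def test_identity_frame_zero(self, rng):
        system, ref, align, measure = self._setup(rng)
        out = cross_rmsd(ref, ref, align, measure)
        assert out.shape == (1,)
        assert out[0] == pytest.approx(0.0, abs=1e-9)

    def test_align_equals_measure_reduces_to_superpose(self, rng):
        system, ref, align, _ = self._setup(rng)
        frame = Frame(coordinates=random_coords(rng, 10))
        expected = superpose(
            frame.coordinates[align.atom_ids], ref.coordinates[align.atom_ids]
        ).rmsd
        assert cross_rmsd(frame, ref, align, align)[0] == pytest.approx(expected)

    def test_constructed_displacement(self, rng):
        """measure_sel rigidly displaced 2 Å after perfect alignment."""
        system, ref, align, measure = self._setup(rng)
        coords = ref.coordinates.copy()
        coords[measure.atom_ids] += np.array([2.0, 0.0, 0.0])
        out = cross_rmsd(Frame(coordinates=coords), ref, align, measure)
        assert out[0] == pytest.approx(2.0, abs=1e-9)

    def test_atom_count_mismatch_errors(self, rng):
        system, ref, align, measure = self._setup(rng)
        small = Frame(coordinates=random_coords(rng, 6))
        with pytest.raises(ValueError, match="atoms"):
            cross_rmsd(small, ref, align, measure)


def brute_force_energy(frame, system, ids_a, ids_b, terms):
    """Plain python double loop (the oracle), including the switch."""
    ke = terms.coulomb_constant / terms.dielectric
    elec = vdw = 0.0
    for i in ids_a:
        for j in ids_b:
            ai, aj = system.atoms[i], system.atoms[j]
            r = float(np.linalg.norm(frame.coordinates[i] - frame.coordinates[j]))
            rc, ron = terms.nonbonded_cutoff, terms.lj_switch_start
            if terms.use_cutoffs and r >= rc:
                continue
            elec += ke * ai.charge * aj.charge / r
            rmin = ai.lj_rmin_half + aj.lj_rmin_half
            eps = np.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            sr6 = (rmin / r) ** 6
            e = eps * (sr6 * sr6 - 2 * sr6)
            if terms.use_cutoffs and r > ron:
                a2, b2 = rc * rc - r * r, rc * rc + 2 * r * r - 3 * ron * ron
                e *= a2 * a2 * b2 / (rc * rc - ron * ron) ** 3
            vdw += e
    return elec, vdw


class TestInteractionEnergy:
    def test_unit_charges_at_one_angstrom(self):
        system = make_beads(2, charges=[1.0, 1.0], epsilon=0.0)
        frame = Frame(coordinates=np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        elec, vdw = interaction_energy(
            frame, system, np.array([0]), np.array([1]), ForceFieldTerms(dielectric=1.0)
        )
        assert elec == pytest.approx(COULOMB_K)
        assert vdw == pytest.approx(0.0)

    def test_lj_pair_at_rmin(self):
        system = make_beads(2, rmin_half=2.1, epsilon=0.4)
        frame = Frame(coordinates=np.array([[0.0, 0, 0], [4.2, 0, 0]]))
        _, vdw = interaction_energy(
            frame, system, np.array([0]), np.array([1]), ForceFieldTerms(dielectric=1.0)
        )
        assert vdw == pytest.approx(-0.4)

    @pytest.mark.parametrize("use_cutoffs", [False, True])
    def test_matches_bruteforce_double_loop(self, toy_complex, rng, use_cutoffs):
        system, start, _ = toy_complex
        terms = ForceFieldTerms(use_cutoffs=use_cutoffs)
        # jitter the start frame so some pairs straddle the switch region
        frame = Frame(coordinates=start.coordinates + rng.normal(0, 0.3, start.coordinates.shape))
        ids_a = system.component_ids(Component.RECEPTOR)
        ids_b = system.component_ids(Component.LIGAND)
        elec, vdw = interaction_energy(frame, system, ids_a, ids_b, terms)
        belec, bvdw = brute_force_energy(frame, system, ids_a, ids_b, terms)
        assert elec == pytest.approx(belec, rel=1e-9)
        assert vdw == pytest.approx(bvdw, rel=1e-9)

    def test_overlapping_groups_rejected(self, toy_complex):
        system, start, _ = toy_complex
        with pytest.raises(ValueError, match="disjoint"):
            interaction_energy(start, system, np.array([0, 1]), np.array([1, 2]))


class TestPerResidueProfile:
    def _mini_complex(self, rng):
        """3-residue 'peptide' (2 beads each) vs a 4-bead 'ligand'."""
        from sumdkit import AtomRecord, MolecularSystem

        atoms = []
        for i in range(6):
            atoms.append(
                AtomRecord(
                    atom_id=i, name="CA", mass=12.0,
                    charge=[1.0, 0.0, -1.0, 0.5, 0.0, -0.5][i],
                    lj_rmin_half=2.0, lj_epsilon=0.2,
                    residue_index=i // 2 + 1, residue_name="AAA",
                    chain_id="P", component=Component.RECEPTOR,
                )
            )
        for j in range(4):
            atoms.append(
                AtomRecord(
                    atom_id=6 + j, name="P", mass=30.0, charge=-1.0 if j % 2 else 1.0,
                    lj_rmin_half=2.2, lj_epsilon=0.1,
                    residue_index=j + 1, residue_name="LIG",
                    chain_id="L", component=Component.LIGAND,
                )
            )
        system = MolecularSystem(atoms=atoms)
        frames = [
            Frame(coordinates=random_coords(rng, 10), time=float(k + 1))
            for k in range(3)
        ]
        return system, Trajectory(system=system, frames=frames)

    def test_rows_sum_to_total(self, rng):
        system, traj = self._mini_complex(rng)
        terms = ForceFieldTerms()
        mat = per_residue_profile(traj, system, Component.RECEPTOR, terms)
        series = interaction_energy_series(traj, system, terms)
        assert np.allclose(mat.matrix.sum(axis=0), series.total, rtol=1e-6)

    def test_matches_per_residue_bruteforce(self, rng):
        system, traj = self._mini_complex(rng)
        terms = ForceFieldTerms()
        mat = per_residue_profile(traj, system, Component.RECEPTOR, terms)
        lig = system.component_ids(Component.LIGAND)
        for r, key in enumerate(mat.residue_keys):
            ids_r = np.array(
                [a.atom_id for a in system.atoms
                 if (a.chain_id, a.residue_index) == key]
            )
            for f_idx, frame in enumerate(traj):
                be, bv = brute_force_energy(frame, system, ids_r, lig, terms)
                assert mat.matrix[r, f_idx] == pytest.approx(be + bv, rel=1e-9)

    def test_uncharged_apolar_residue_zero_row(self, rng):
        system, traj = self._mini_complex(rng)
        import dataclasses

        atoms = [
            dataclasses.replace(a, charge=0.0, lj_epsilon=0.0)
            if a.residue_index == 2 and a.component is Component.RECEPTOR
            else a
            for a in system.atoms
        ]
        from sumdkit import MolecularSystem

        system2 = MolecularSystem(atoms=atoms)
        traj2 = Trajectory(system=system2, frames=traj.frames)
        mat = per_residue_profile(traj2, system2, Component.RECEPTOR)
        row = mat.matrix[[k == ("P", 2) for k in mat.residue_keys]]
        assert np.allclose(row, 0.0)


class TestContactTable:
    def _pair_system(self, separation):
        from sumdkit import AtomRecord, MolecularSystem

        atoms = [
            AtomRecord(0, "P", 10.0, 0.0, 2.0, 0.1, 1, "RNB", "R", Component.RECEPTOR),
            AtomRecord(1, "CA", 10.0, 0.0, 2.0, 0.1, 1, "COR", "P", Component.LIGAND),
        ]
        system = MolecularSystem(atoms=atoms)
        frame = Frame(coordinates=np.array([[0.0, 0, 0], [separation, 0, 0]]), time=1.0)
        return system, Trajectory(system=system, frames=[frame])

    def test_cutoff_boundary_4p4_in_4p6_out(self):
        system, traj = self._pair_system(4.4)
        table = contact_table(traj, system)
        assert table.cutoff == 4.5  # the documented default
        assert table.receptor[("R", 1)] == 1.0
        system, traj = self._pair_system(4.6)
        table = contact_table(traj, system)
        assert table.receptor[("R", 1)] == 0.0

    def test_default_top_k_is_25(self, toy_complex):
        import inspect

        assert inspect.signature(contact_table).parameters["top_k"].default == 25

    def test_matches_bruteforce_counting(self, toy_complex, rng):
        system, start, bound = toy_complex
        frames = [
            Frame(coordinates=bound.coordinates + rng.normal(0, 0.5, bound.coordinates.shape),
                  time=float(k + 1))
            for k in range(4)
        ]
        traj = Trajectory(system=system, frames=frames)
        cutoff = 6.0
        table = contact_table(traj, system, cutoff=cutoff, top_k=1000)
        rec_ids = system.component_ids(Component.RECEPTOR)
        lig_ids = system.component_ids(Component.LIGAND)
        for key, freq in table.receptor.items():
            count = 0
            ids_r = [i for i in rec_ids
                     if (system.atoms[i].chain_id, system.atoms[i].residue_index) == key]
            for frame in traj:
                hit = False
                for i in ids_r:
                    for j in lig_ids:
                        if np.linalg.norm(frame.coordinates[i] - frame.coordinates[j]) <= cutoff:
                            hit = True
                assert hit in (True, False)
                count += hit
            assert freq == pytest.approx(count / len(traj))

    def test_monotone_in_cutoff(self, toy_complex, rng):
        system, _, bound = toy_complex
        traj = Trajectory(system=system, frames=[Frame(coordinates=bound.coordinates, time=1.0)])
        t1 = contact_table(traj, system, cutoff=4.0, top_k=1000)
        t2 = contact_table(traj, system, cutoff=7.0, top_k=1000)
        for key, f in t1.receptor.items():
            assert t2.receptor[key] >= f


class TestReplicaMetrics:
    def test_constant_trajectory_zero_sd(self, toy_complex):
        system, _, bound = toy_complex
        frames = [Frame(coordinates=bound.coordinates, time=float(k + 1)) for k in range(3)]
        traj = Trajectory(system=system, frames=frames)
        align = build_selection(system, "component receptor")
        measure = build_selection(system, "component ligand")
        m = replica_metrics(traj, system, align, measure)
        assert m.sd_rmsd == pytest.approx(0.0, abs=1e-9)
        assert m.sd_energy == pytest.approx(0.0, abs=1e-9)
        assert m.mean_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_two_frame_hand_arithmetic(self, toy_complex):
        system, _, bound = toy_complex
        lig = system.component_ids(Component.LIGAND)
        x2 = bound.coordinates.copy()
        x2[lig] += np.array([3.0, 0.0, 0.0])
        frames = [Frame(coordinates=bound.coordinates, time=1.0), Frame(coordinates=x2, time=2.0)]
        traj = Trajectory(system=system, frames=frames)
        align = build_selection(system, "component receptor")
        measure = build_selection(system, "component ligand")
        m = replica_metrics(traj, system, align, measure)
        # frame 1: rmsd 0; frame 2: rigid 3 Å shift of the measured group
        assert m.mean_rmsd == pytest.approx(1.5, abs=1e-6)
        assert m.sd_rmsd == pytest.approx(1.5, abs=1e-6)  # population sd
        e = interaction_energy_series(traj, system).total
        assert m.mean_energy == pytest.approx(e.mean())
        assert m.sd_energy == pytest.approx(e.std())

    def test_rigid_motion_invariance(self, toy_complex, rng):
        system, _, bound = toy_complex
        frames = [
            Frame(coordinates=bound.coordinates + rng.normal(0, 0.2, bound.coordinates.shape),
                  time=float(k + 1))
            for k in range(3)
        ]
        traj = Trajectory(system=system, frames=frames)
        R = rotation_z(0.7)
        moved = [
            Frame(coordinates=f.coordinates @ R.T + np.array([5.0, -2.0, 1.0]), time=f.time)
            for f in frames
        ]
        traj2 = Trajectory(system=system, frames=moved)
        align = build_selection(system, "component receptor")
        measure = build_selection(system, "component ligand")
        m1 = replica_metrics(traj, system, align, measure)
        m2 = replica_metrics(traj2, system, align, measure)
        assert m1.mean_rmsd == pytest.approx(m2.mean_rmsd, abs=1e-8)
        assert m1.mean_energy == pytest.approx(m2.mean_energy, rel=1e-9)


def _metric(rid, rmsd, energy):
    return ReplicaMetrics(rid, rmsd, 0.0, energy, 0.0)


class TestRankReplicas:
    def test_best_on_both_axes_wins(self):
        # three stability replicas: lowest mean RMSD + most favourable energy
        runs = [
            _metric("Run1", 3.35, -452.9),
            _metric("Run2", 6.61, -336.9),
            _metric("Run3", 15.78, -358.5),
        ]
        ranked = rank_replicas(runs)
        assert ranked[0].replica_id == "Run1"

    def test_identical_metrics_keep_input_order(self):
        runs = [_metric("a", 2.0, -10.0), _metric("b", 2.0, -10.0)]
        assert [m.replica_id for m in rank_replicas(runs)] == ["a", "b"]

    def test_composite_rank_arithmetic(self):
        # x best on RMSD (rank 1 + 2 = 3), y best on energy (rank 2 + 1 = 3),
        # tie broken by mean energy → y first; z strictly worst
        x = _metric("x", 1.0, -5.0)
        y = _metric("y", 2.0, -20.0)
        z = _metric("z", 3.0, -1.0)
        assert [m.replica_id for m in rank_replicas([x, y, z])] == ["y", "x", "z"]
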