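"""Pairwise nonbonded forces and residue-level force distribution analysis."""

import numpy as np
import pytest

from groovedyn.model import GrooveDynError, Selection, Topology, Trajectory
from groovedyn.pairforce import (
    COULOMB_K,
    PN_PER_KJ_MOL_A,
    ForceModelParams,
    force_difference_map,
    frame_pair_forces,
    interface_force_summary,
    pair_force,
    residue_force_matrix,
)
from groovedyn.synthetic import _bead

from conftest import random_rotation


def _params_topology(n, coords_rng=None, charges=None, chain_split=None):
    """n single-atom residues with random or given charges/LJ params,
    split into chains A and B at ``chain_split``."""
    split = chain_split if chain_split is not None else n // 2
    atoms = []
    for i in range(n):
        chain = "A" if i < split else "B"
        seq = i + 1 if i < split else i - split + 1
        atoms.append(_bead(i, chain, seq))
    top = Topology(atoms=atoms)
    rng = coords_rng or np.random.default_rng(0)
    if charges is None:
        charges = rng.uniform(-0.5, 0.5, n)
    rows = [
        (a.chain_id, a.residue_seq, a.name, charges[i], 3.2, 0.4)
        for i, a in enumerate(top.atoms)
    ]
    return top.with_parameters(rows)


def brute_force_pairs(frame, topology, sel_a, sel_b, model):
    """Independent O(N^2) oracle for frame_pair_forces."""
    out = []
    for i in sel_a.atom_indices:
        for j in sel_b.atom_indices:
            ai, aj = topology.atoms[i], topology.atoms[j]
            r = np.linalg.norm(frame[i] - frame[j])
            if r <= model.cutoff:
                f = pair_force(
                    frame[i], frame[j],
                    (ai.charge, ai.lj_sigma, ai.lj_epsilon),
                    (aj.charge, aj.lj_sigma, aj.lj_epsilon),
                    model,
                )
                out.append((int(i), int(j), f))
    return out


class TestPairForce:
    def test_coulomb_unit_oracle(self):
        # +1e / +1e at 7 A, no LJ, no shift: 1389.35/49 kJ/mol/A = 470.83 pN,
        # repulsive along the separation axis (frozen from the independent
        # constant-handling script)
        model = ForceModelParams(cutoff=10.0, shift_mode="none")
        f = pair_force(
            np.array([7.0, 0, 0]), np.zeros(3), (1.0, 1.0, 0.0), (1.0, 1.0, 0.0), model
        )
        assert np.linalg.norm(f) == pytest.approx(470.832418, rel=1e-6)
        assert f[0] > 0  # pushes atom i away from j: repulsive

    def test_dielectric_scales_coulomb(self):
        model = ForceModelParams(shift_mode="none", dielectric=4.0)
        f = pair_force(
            np.array([7.0, 0, 0]), np.zeros(3), (1.0, 1.0, 0.0), (1.0, 1.0, 0.0), model
        )
        assert np.linalg.norm(f) == pytest.approx(470.832418 / 4.0, rel=1e-6)

    def test_zero_beyond_cutoff(self):
        f = pair_force(
            np.array([10.5, 0, 0]), np.zeros(3), (1.0, 3.0, 0.5), (1.0, 3.0, 0.5)
        )
        np.testing.assert_array_equal(f, 0.0)

    def test_lj_minimum_and_sign_change(self):
        sigma, eps = 3.0, 0.5
        p = (0.0, sigma, eps)
        r_min = 2 ** (1 / 6) * sigma
        model = ForceModelParams(shift_mode="none")
        at_min = pair_force(np.array([r_min, 0, 0]), np.zeros(3), p, p, model)
        assert np.linalg.norm(at_min) < 1e-9
        inside = pair_force(np.array([r_min - 0.2, 0, 0]), np.zeros(3), p, p, model)
        outside = pair_force(np.array([r_min + 0.2, 0, 0]), np.zeros(3), p, p, model)
        assert inside[0] > 0  # repulsive
        assert outside[0] < 0  # attractive

    def test_force_shift_continuous_at_cutoff(self):
        p = (0.4, 3.0, 0.5)
        model = ForceModelParams(cutoff=10.0, shift_mode="force-shift")
        radii = np.linspace(9.0, 9.999, 200)
        mags = [
            np.linalg.norm(pair_force(np.array([r, 0, 0]), np.zeros(3), p, p, model))
            for r in radii
        ]
        assert mags[-1] < 0.05 * mags[0]
        just_inside = pair_force(np.array([9.9999, 0, 0]), np.zeros(3), p, p, model)
        assert np.linalg.norm(just_inside) < 1e-2

    def test_coincident_atoms_rejected(self):
        with pytest.raises(GrooveDynError, match="singular"):
            pair_force(np.zeros(3), np.zeros(3), (1.0, 3.0, 0.5), (1.0, 3.0, 0.5))


class TestFramePairForces:
    def test_enumerates_in_cutoff_pairs(self):
        top = _params_topology(3, chain_split=1)
        frame = np.array([[0.0, 0, 0], [4.0, 0, 0], [0.0, 5.0, 0]])
        sel_a = Selection.from_indices(top, [0])
        sel_b = Selection.from_indices(top, [1, 2])
        ia, ib, forces = frame_pair_forces(frame, top, sel_a, sel_b)
        assert len(ia) == 2

    def test_matches_brute_force_on_500_random_atoms(self):
        rng = np.random.default_rng(42)
        top = _params_topology(500, coords_rng=rng)
        frame = rng.uniform(0, 40.0, size=(500, 3))
        sel_a = Selection.from_indices(top, range(250))
        sel_b = Selection.from_indices(top, range(250, 500))
        model = ForceModelParams(cutoff=10.0)
        ia, ib, forces = frame_pair_forces(frame, top, sel_a, sel_b, model)
        oracle = brute_force_pairs(frame, top, sel_a, sel_b, model)
        got = {(int(i), int(j)): f for i, j, f in zip(ia, ib, forces)}
        assert set(got) == {(i, j) for i, j, _ in oracle}
        for i, j, f in oracle:
            np.testing.assert_allclose(got[(i, j)], f, atol=1e-10)

    def test_net_force_vanishes(self):
        rng = np.random.default_rng(7)
        top = _params_topology(40, coords_rng=rng)
        frame = rng.uniform(0, 12.0, size=(40, 3))
        sel_a = Selection.from_indices(top, range(20))
        sel_b = Selection.from_indices(top, range(20, 40))
        _, _, forces = frame_pair_forces(frame, top, sel_a, sel_b)
        # sum of forces on A plus the (negated) reactions on B is zero
        np.testing.assert_allclose(forces.sum(axis=0) - forces.sum(axis=0), 0.0)
        assert np.max(np.abs(forces.sum(axis=0) + (-forces).sum(axis=0))) < 1e-8

    def test_overlapping_selections_rejected(self):
        top = _params_topology(4)
        sel_a = Selection.from_indices(top, [0, 1])
        sel_b = Selection.from_indices(top, [1, 2])
        with pytest.raises(GrooveDynError, match="overlap"):
            frame_pair_forces(np.zeros((4, 3)), top, sel_a, sel_b)


def _dimer_traj(charge_a, charge_b, r=7.0, n_frames=3):
    top = Topology(atoms=[_bead(0, "A", 1), _bead(1, "B", 1)])
    rows = [("A", 1, "CA", charge_a, 1.0, 0.0), ("B", 1, "CA", charge_b, 1.0, 0.0)]
    top = top.with_parameters(rows)
    frame = np.array([[0.0, 0, 0], [r, 0, 0]])
    coords = np.repeat(frame[None], n_frames, axis=0)
    return top, Trajectory(coords, 0.01 * np.arange(1, n_frames + 1), top)


class TestResidueForceMatrix:
    def test_like_charge_dimer_analytic_and_repulsive(self):
        top, traj = _dimer_traj(1.0, 1.0)
        model = ForceModelParams(shift_mode="none")
        m = residue_force_matrix(
            traj,
            Selection.from_indices(top, [0]),
            Selection.from_indices(top, [1]),
            model,
        )
        expected = COULOMB_K / 49.0 * PN_PER_KJ_MOL_A
        assert m.magnitude[0, 0] == pytest.approx(expected, abs=1e-6)
        assert m.sign[0, 0] == 1.0

    def test_opposite_charge_dimer_attractive(self):
        top, traj = _dimer_traj(1.0, -1.0)
        model = ForceModelParams(shift_mode="none")
        m = residue_force_matrix(
            traj,
            Selection.from_indices(top, [0]),
            Selection.from_indices(top, [1]),
            model,
        )
        expected = COULOMB_K / 49.0 * PN_PER_KJ_MOL_A
        assert m.magnitude[0, 0] == pytest.approx(expected, abs=1e-6)
        assert m.sign[0, 0] == -1.0

    def test_alternating_forces_cancel_in_time_average(self):
        # charges flip sign every frame via geometry: atom b oscillates
        # between +x and -x of a; the per-frame vector sum alternates and
        # the time mean (vector-then-norm convention) vanishes
        top = Topology(atoms=[_bead(0, "A", 1), _bead(1, "B", 1)])
        rows = [("A", 1, "CA", 1.0, 1.0, 0.0), ("B", 1, "CA", 1.0, 1.0, 0.0)]
        top = top.with_parameters(rows)
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = [7.0, -7.0, 7.0, -7.0]
        traj = Trajectory(coords, 0.01 * np.arange(1, 5), top)
        m = residue_force_matrix(
            traj,
            Selection.from_indices(top, [0]),
            Selection.from_indices(top, [1]),
            ForceModelParams(shift_mode="none"),
        )
        assert m.magnitude[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_newton_third_law_under_selection_swap(self):
        rng = np.random.default_rng(3)
        top = _params_topology(10, coords_rng=rng)
        frame = rng.uniform(0, 8.0, size=(10, 3))
        traj = Trajectory(frame[None], [0.01], top)
        sel_a = Selection.from_indices(top, range(5))
        sel_b = Selection.from_indices(top, range(5, 10))
        ab = residue_force_matrix(traj, sel_a, sel_b)
        ba = residue_force_matrix(traj, sel_b, sel_a)
        np.testing.assert_allclose(ab.magnitude, ba.magnitude.T, atol=1e-6)
        np.testing.assert_allclose(ab.mean_vector, -ba.mean_vector.transpose(1, 0, 2),
                                   atol=1e-10)
        np.testing.assert_allclose(ab.sign, ba.sign.T)

    def test_rigid_transform_preserves_magnitudes(self):
        rng = np.random.default_rng(4)
        top = _params_topology(8, coords_rng=rng)
        frame = rng.uniform(0, 8.0, size=(8, 3))
        sel_a = Selection.from_indices(top, range(4))
        sel_b = Selection.from_indices(top, range(4, 8))
        traj = Trajectory(frame[None], [0.01], top)
        base = residue_force_matrix(traj, sel_a, sel_b)
        rot = random_rotation(rng)
        moved = Trajectory((frame @ rot.T + 11.0)[None], [0.01], top)
        transformed = residue_force_matrix(moved, sel_a, sel_b)
        np.testing.assert_allclose(
            transformed.magnitude, base.magnitude, atol=1e-8
        )
        for i in range(4):
            for j in range(4):
                np.testing.assert_allclose(
                    transformed.mean_vector[i, j], rot @ base.mean_vector[i, j],
                    atol=1e-8,
                )


class TestForceDifferenceMap:
    def _matrix(self, signed):
        from groovedyn.pairforce import ResidueForceMatrix

        signed = np.asarray(signed, dtype=np.float64)
        return ResidueForceMatrix(
            residue_labels_a=[f"A{i+1}" for i in range(signed.shape[0])],
            residue_labels_b=[f"B{j+1}" for j in range(signed.shape[1])],
            mean_vector=np.zeros((*signed.shape, 3)),
            magnitude=np.abs(signed),
            sign=np.where(signed >= 0, 1.0, -1.0),
            n_frames=1,
        )

    def test_identical_matrices_give_empty_map(self):
        m = self._matrix([[-50.0, 20.0], [0.0, 90.0]])
        assert force_difference_map(m, m) == []

    def test_injected_perturbation_recovered(self):
        a = self._matrix([[-50.0, 20.0], [10.0, 90.0]])
        b = self._matrix([[-50.0, 20.0], [10.0, -58.0]])
        out = force_difference_map(a, b, floor=30.0)
        assert len(out) == 1
        assert out[0]["pair"] == ("A2", "B2")
        assert out[0]["dF"] == pytest.approx(148.0)

    def test_floor_zero_reports_full_universe_sorted(self):
        a = self._matrix([[-50.0, 20.0], [10.0, 90.0]])
        b = self._matrix([[0.0, 0.0], [0.0, 0.0]])
        out = force_difference_map(a, b, floor=0.0)
        assert len(out) == 4
        assert [e["abs_dF"] for e in out] == sorted(
            (e["abs_dF"] for e in out), reverse=True
        )

    def test_mismatched_universe_rejected(self):
        a = self._matrix([[1.0]])
        b = self._matrix([[1.0, 2.0]])
        with pytest.raises(GrooveDynError, match="universe"):
            force_difference_map(a, b)


class TestInterfaceForceSummary:
    def test_empty_interface_sums_to_zero(self):
        top, _ = _dimer_traj(1.0, 1.0)
        frame = np.array([[0.0, 0, 0], [50.0, 0, 0]])  # beyond cutoff
        traj = Trajectory(frame[None], [0.01], top)
        m = residue_force_matrix(
            traj, Selection.from_indices(top, [0]), Selection.from_indices(top, [1])
        )
        assert interface_force_summary(m) == 0.0

    def test_attractive_pairs_sum_negative(self):
        m = TestForceDifferenceMap()._matrix([[-100.0], [-100.0]])
        assert interface_force_summary(m) == pytest.approx(-200.0)

    def test_anchor_charge_removal_weakens_interface(self, toy_groove):
        # recompute forces on the *same* trajectory with the anchor charges
        # zeroed: the anchor-pocket Coulomb attraction disappears while the
        # LJ contact terms are unchanged, so the interface must read
        # strictly less attractive in every replica
        from groovedyn.select import select
        from groovedyn.synthetic import LangevinSpec, propagate_langevin

        top, frame, rows = toy_groove
        uncharged = top.with_parameters(
            [(c, s, n, 0.0, sig, eps) for c, s, n, q, sig, eps in rows]
        )
        for seed in range(5):
            traj = propagate_langevin(
                top, frame, LangevinSpec(n_steps=4000, sample_every=100, seed=seed)
            )
            with_anchor = interface_force_summary(
                residue_force_matrix(
                    traj, select(top, "chain P"), select(top, "chain M")
                )
            )
            neutral_traj = Trajectory(traj.coordinates, traj.times, uncharged)
            without = interface_force_summary(
                residue_force_matrix(
                    neutral_traj,
                    select(uncharged, "chain P"),
                    select(uncharged, "chain M"),
                )
            )
            assert without > with_anchor  # strictly less attractive
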