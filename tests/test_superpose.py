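"""Kabsch fitting, RMSD/RMSF analyses and dissociation classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from groovedyn.model import Selection, Topology, Trajectory
from groovedyn.select import select
from groovedyn.superpose import (
    DegenerateFitError,
    block_bootstrap_sem,
    bound_fraction_both_termini,
    dissociation_profile,
    fit_trajectory,
    flag_full_dissociation,
    kabsch_fit,
    moving_average,
    residue_rmsd_series,
    rmsf,
)
from groovedyn.synthetic import TwoStateSpec, generate_two_state

from conftest import random_rotation


def _rmsd(a, b):
    return np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))


class TestKabsch:
    def test_identity_on_equal_point_sets(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        tf = kabsch_fit(pts, pts)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-10)

    def test_recovers_constructed_transform(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(12, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot90.T + np.array([1.0, 2.0, 3.0])
        tf = kabsch_fit(mobile, ref)
        assert _rmsd(tf.apply(mobile), ref) < 1e-6

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(20, 3))
        mobile = ref @ random_rotation(rng).T + rng.normal(size=3)
        mobile += rng.normal(scale=0.05, size=mobile.shape)
        tf = kabsch_fit(mobile, ref)
        rot_sp, _ = Rotation.align_vectors(
            ref - ref.mean(axis=0), mobile - mobile.mean(axis=0)
        )
        np.testing.assert_allclose(tf.rotation, rot_sp.as_matrix(), atol=1e-8)

    def test_beats_random_rotations(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(10, 3))
        mobile = ref @ random_rotation(rng).T + rng.normal(scale=0.1, size=(10, 3))
        tf = kabsch_fit(mobile, ref)
        best = _rmsd(tf.apply(mobile), ref)
        mob_c = mobile - mobile.mean(axis=0)
        ref_centroid = ref.mean(axis=0)
        for _ in range(1000):
            cand = mob_c @ random_rotation(rng).T + ref_centroid
            assert best <= _rmsd(cand, ref) + 1e-12

    def test_fit_rmsd_invariant_under_rigid_pretransform(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(8, 3))
        mobile = ref + rng.normal(scale=0.2, size=(8, 3))
        base = _rmsd(kabsch_fit(mobile, ref).apply(mobile), ref)
        moved = mobile @ random_rotation(rng).T + np.array([5.0, -3.0, 2.0])
        again = _rmsd(kabsch_fit(moved, ref).apply(moved), ref)
        assert abs(base - again) < 1e-6

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateFitError):
            kabsch_fit(pts, pts + 1.0)

    def test_weighted_fit_prefers_heavy_points(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mobile = ref.copy()
        mobile[3] += [0.0, 0.0, 2.0]  # outlier
        w = np.array([1.0, 1.0, 1.0, 1e-9])
        tf = kabsch_fit(mobile, ref, weights=w)
        assert _rmsd(tf.apply(mobile)[:3], ref[:3]) < 1e-6


def _ca_chain(n=5, chain="P"):
    from groovedyn.synthetic import _bead

    top = Topology(atoms=[_bead(i, chain, i + 1) for i in range(n)])
    base = np.zeros((n, 3))
    base[:, 0] = 3.8 * np.arange(n)
    base[:, 1] = 1.5 * (np.arange(n) % 2)  # zig-zag: fit points not collinear
    base[:, 2] = 0.8 * (np.arange(n) % 3)
    return top, base


class TestFitTrajectory:
    def test_pure_rigid_motion_removed(self):
        top, base = _ca_chain(6)
        rng = np.random.default_rng(4)
        frames = [
            base @ random_rotation(rng).T + rng.normal(size=3) for _ in range(10)
        ]
        traj = Trajectory(np.array(frames), 0.01 * np.arange(1, 11), top)
        sel = select(top, "name CA")
        fitted = fit_trajectory(traj, base, sel)
        for f in range(10):
            assert _rmsd(fitted.coordinates[f], base) < 1e-6

    def test_idempotent(self):
        top, base = _ca_chain(6)
        rng = np.random.default_rng(5)
        traj = Trajectory(
            base + rng.normal(scale=0.3, size=(7, 6, 3)),
            0.01 * np.arange(1, 8),
            top,
        )
        sel = select(top, "name CA")
        once = fit_trajectory(traj, base, sel)
        twice = fit_trajectory(once, base, sel)
        np.testing.assert_allclose(twice.coordinates, once.coordinates, atol=1e-8)

    def test_fitted_rmsd_never_exceeds_unfitted(self):
        top, base = _ca_chain(8)
        rng = np.random.default_rng(6)
        coords = base + rng.normal(scale=0.5, size=(50, 8, 3))
        coords += rng.normal(scale=2.0, size=(50, 1, 3))  # random frame offsets
        traj = Trajectory(coords, 0.01 * np.arange(1, 51), top)
        fitted = fit_trajectory(traj, base, select(top, "name CA"))
        for f in range(50):
            assert _rmsd(fitted.coordinates[f], base) <= _rmsd(coords[f], base) + 1e-9


class TestResidueRmsdSeries:
    def test_zero_for_reference_frames(self):
        top, base = _ca_chain(5)
        traj = Trajectory(np.array([base, base]), [0.01, 0.02], top)
        labels, s = residue_rmsd_series(traj, base, select(top, "name CA"))
        assert labels == ["G1", "G2", "G3", "G4", "G5"]
        np.testing.assert_allclose(s, 0.0)

    def test_single_displaced_atom_reads_exactly(self):
        top, base = _ca_chain(5)
        frame2 = base.copy()
        frame2[2, 2] += 3.0
        traj = Trajectory(np.array([base, frame2]), [0.01, 0.02], top)
        _, s = residue_rmsd_series(traj, base, select(top, "name CA"))
        assert s[1, 2] == pytest.approx(3.0)
        assert np.count_nonzero(s > 1e-12) == 1

    def test_two_state_mixture_mean(self):
        # closed-form: E[RMSD] = p_b * E|noise| + p_u * E|d + noise|
        # with E|noise| = 2 sigma sqrt(2/pi) (chi_3 mean) and the displaced
        # branch approximated by sqrt(d^2 + 3 sigma^2) for d >> sigma
        spec = TwoStateSpec(
            k_off=4.0, k_on=1.0, displacement=8.0, noise_sigma=0.3,
            frame_dt_ns=1.0, n_frames=100_000, seed=11, n_residues=1,
        )
        top, traj, states, pi_bound = generate_two_state(spec)
        _, s = residue_rmsd_series(traj, np.zeros((1, 3)), select(top, "name CA"))
        p_b = pi_bound[0]
        e_bound = 2 * 0.3 * np.sqrt(2 / np.pi)
        e_unbound = np.sqrt(8.0**2 + 3 * 0.3**2)
        expected = p_b * e_bound + (1 - p_b) * e_unbound
        assert s.mean() == pytest.approx(expected, rel=0.05)


class TestDissociationProfile:
    def test_all_bound_when_rmsd_zero(self):
        profile = dissociation_profile([np.zeros((10, 3))], ["E1", "R5", "F9"])
        np.testing.assert_allclose(profile.bound_fraction, 1.0)
        np.testing.assert_allclose(profile.mean_rmsd, 0.0)

    def test_bound_fraction_counts_threshold_ties_as_bound(self):
        s = np.zeros((8, 2))
        s[:2, 0] = 5.0  # 25% above threshold for residue 0
        s[2, 0] = 3.0  # exactly at threshold: bound
        profile = dissociation_profile([s], ["A1", "A2"], threshold=3.0)
        assert profile.bound_fraction[0] == pytest.approx(0.75)
        assert profile.bound_fraction[1] == 1.0

    def test_replica_equal_weighting(self):
        a = np.full((10, 1), 1.0)
        b = np.full((90, 1), 3.0)
        profile = dissociation_profile([a, b], ["X1"])
        # frames-then-replicas: (1 + 3)/2, not the pooled 2.8
        assert profile.mean_rmsd[0] == pytest.approx(2.0)

    def test_two_state_occupancy_recovered(self):
        spec = TwoStateSpec(
            k_off=4.0, k_on=1.0, frame_dt_ns=10.0, n_frames=60_000,
            seed=13, n_residues=1,
        )
        top, traj, states, pi_bound = generate_two_state(spec)
        ref = np.zeros((1, 3))
        _, s = residue_rmsd_series(traj, ref, select(top, "name CA"))
        profile = dissociation_profile([s], ["G1"])
        se = block_bootstrap_sem(profile.bound_mask[0][:, 0].astype(float), seed=1)
        assert abs(profile.bound_fraction[0] - 0.2) < 3 * se

    def test_both_termini_independent_product(self):
        # marginals 0.5 and 0.4 on independent chains -> joint 0.2
        spec = TwoStateSpec(
            k_off=np.array([2.0, 3.0]), k_on=np.array([2.0, 2.0]),
            frame_dt_ns=10.0, n_frames=60_000, seed=17, n_residues=2,
        )
        top, traj, states, pi_bound = generate_two_state(spec)
        np.testing.assert_allclose(pi_bound, [0.5, 0.4])
        ref = np.zeros((2, 3))
        ref[1, 0] = 3.8
        _, s = residue_rmsd_series(traj, ref, select(top, "name CA"))
        profile = dissociation_profile([s], ["G1", "G2"])
        joint = bound_fraction_both_termini(profile, "G1", "G2")
        assert joint == pytest.approx(0.2, abs=0.02)

    def test_both_termini_trivial_cases(self):
        always = dissociation_profile([np.zeros((10, 2))], ["N", "C"])
        assert bound_fraction_both_termini(always, "N", "C") == 1.0
        s = np.zeros((10, 2))
        s[:5, 0] = 9.0
        s[5:, 1] = 9.0  # disjoint bound sets
        disjoint = dissociation_profile([s], ["N", "C"])
        assert bound_fraction_both_termini(disjoint, "N", "C") == 0.0


class TestRmsf:
    def test_frozen_trajectory_is_zero(self):
        top, base = _ca_chain(4)
        traj = Trajectory(np.array([base] * 5), 0.01 * np.arange(1, 6), top)
        per_atom, _, per_res = rmsf(traj, select(top, "name CA"))
        np.testing.assert_allclose(per_atom, 0.0)
        np.testing.assert_allclose(per_res, 0.0)

    def test_isotropic_jitter_recovers_sigma_sqrt3(self):
        top, base = _ca_chain(3)
        rng = np.random.default_rng(21)
        sigma = 0.5
        coords = base + rng.normal(scale=sigma, size=(100_000, 3, 3))
        traj = Trajectory(coords, 0.01 * np.arange(1, 100_001), top)
        per_atom, _, _ = rmsf(traj, select(top, "name CA"))
        np.testing.assert_allclose(per_atom, sigma * np.sqrt(3), rtol=0.02)

    def test_invariant_under_global_rigid_transform_before_fitting(self):
        top, base = _ca_chain(6)
        rng = np.random.default_rng(22)
        coords = base + rng.normal(scale=0.4, size=(200, 6, 3))
        traj = Trajectory(coords, 0.01 * np.arange(1, 201), top)
        sel = select(top, "name CA")
        rot = random_rotation(rng)
        moved = Trajectory(coords @ rot.T + 7.0, traj.times, top)
        a = rmsf(fit_trajectory(traj, base, sel), sel)[0]
        b = rmsf(fit_trajectory(moved, base, sel), sel)[0]
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_null_delta_rmsf_within_bootstrap_error(self):
        top, base = _ca_chain(3)
        sel = select(top, "name CA")

        def ensemble(seed):
            rng = np.random.default_rng(seed)
            coords = base + rng.normal(scale=0.5, size=(20_000, 3, 3))
            return Trajectory(coords, 0.01 * np.arange(1, 20_001), top)

        a = ensemble(1)
        b = ensemble(2)
        delta = rmsf(a, sel)[0] - rmsf(b, sel)[0]
        for i, (ai, bi) in enumerate(zip(a.coordinates.transpose(1, 0, 2),
                                         b.coordinates.transpose(1, 0, 2))):
            da = np.linalg.norm(ai - ai.mean(axis=0), axis=1)
            db = np.linalg.norm(bi - bi.mean(axis=0), axis=1)
            se = np.hypot(block_bootstrap_sem(da, seed=3), block_bootstrap_sem(db, seed=4))
            assert abs(delta[i]) < 3 * se

    def test_single_frame_rejected(self):
        top, base = _ca_chain(3)
        traj = Trajectory(base[None], [0.01], top)
        with pytest.raises(Exception, match="single frame"):
            rmsf(traj, select(top, "name CA"))


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        s = np.full(50, 2.5)
        np.testing.assert_allclose(moving_average(s, 1.0, 0.1), s)

    def test_unit_impulse_box_filter(self):
        s = np.zeros(51)
        s[25] = 1.0
        out = moving_average(s, 0.5, 0.1)  # 5-frame window
        np.testing.assert_allclose(out[23:28], 0.2)
        assert out[22] == 0.0 and out[28] == 0.0

    def test_white_noise_variance_reduction(self):
        rng = np.random.default_rng(30)
        s = rng.standard_normal(200_000)
        out = moving_average(s, 1.0, 0.01)  # 100-frame window
        assert out[5000:-5000].var() == pytest.approx(1 / 100, rel=0.2)

    def test_window_below_frame_spacing_rejected(self):
        with pytest.raises(Exception, match="window"):
            moving_average(np.zeros(10), 0.001, 0.01)


class TestFullDissociationFlag:
    times = np.linspace(0.1, 1000.0, 10_000)
    labels = ["E1", "F9"]

    def _series(self):
        return np.zeros((10_000, 2))

    def test_bound_replica_not_flagged(self):
        assert not flag_full_dissociation(
            self._series(), self.times, self.labels, "E1", "F9"
        )

    def test_terminal_unbound_suffix_flagged(self):
        s = self._series()
        s[3000:, :] = 9.0  # both termini out for the last ~700 ns
        assert flag_full_dissociation(s, self.times, self.labels, "E1", "F9")

    def test_brief_mid_trajectory_excursion_not_flagged(self):
        s = self._series()
        mid = (self.times > 500) & (self.times < 501)
        s[mid, :] = 9.0
        assert not flag_full_dissociation(
            s, self.times, self.labels, "E1", "F9", persistence_ns=10.0
        )

    def test_short_terminal_excursion_below_persistence_not_flagged(self):
        s = self._series()
        s[self.times > 995, :] = 9.0  # only 5 ns
        assert not flag_full_dissociation(
            s, self.times, self.labels, "E1", "F9", persistence_ns=10.0
        )
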