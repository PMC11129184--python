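"""Perturbation response scanning: covariance, linear response, overlap, scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from memallo.errors import IllPosedError, InsufficientDataError, SelectionError
from memallo import prs, synthetic
from memallo.prs import (
    CovarianceMatrix,
    DisplacementField,
    ForcePerturbation,
    analytic_best_force,
    compute_covariance,
    converged_start,
    linear_response,
    overlap,
    rank_hotspots,
    scan,
    target_displacement,
)
from memallo.trajectory import Structure, Trajectory


def _nodes(n):
    return [("A", i + 1) for i in range(n)]


def _traj_from_frames(frames):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    topo = Structure(
        np.array(["CA"] * n), np.array(["C"] * n), np.arange(1, n + 1),
        np.array(["ALA"] * n), np.array(["A"] * n), frames[0].copy(),
    )
    return Trajectory(topo, frames, np.arange(len(frames), dtype=float))


class TestComputeCovariance:
    def test_zero_variance_gives_zero_matrix(self):
        frame = np.random.default_rng(0).uniform(0, 10, (5, 3))
        traj = _traj_from_frames(np.repeat(frame[None], 4, axis=0))
        C = compute_covariance(traj, "name CA", align=False)
        assert np.allclose(C.matrix, 0.0)
        assert C.matrix.shape == (15, 15)

    def test_matches_generator_truth(self):
        spec = synthetic.GaussianEnsembleSpec(
            10, np.column_stack([np.arange(10) * 3.8, np.zeros(10), np.zeros(10)]),
            synthetic.Isotropic(1.0), 10000, 1,
        )
        traj, _ = synthetic.generate_gaussian_ensemble(spec)
        C = compute_covariance(traj, "name CA", align=False)
        assert abs(np.diag(C.matrix).mean() - 1.0) < 0.05

    def test_two_frame_hand_value(self):
        # node 2 displaced by d along x in frame 1: variance = (d/2)^2
        d = 2.0
        base = np.column_stack([np.arange(5) * 5.0, np.zeros(5), np.zeros(5)])
        frame2 = base.copy()
        frame2[2, 0] += d
        traj = _traj_from_frames([base, frame2])
        C = compute_covariance(traj, "name CA", align=False)
        expected = np.zeros((15, 15))
        expected[6, 6] = d**2 / 4  # population (n) denominator
        np.testing.assert_allclose(C.matrix, expected, atol=1e-12)

    def test_too_few_frames(self):
        traj = _traj_from_frames(np.zeros((1, 5, 3)))
        with pytest.raises(InsufficientDataError):
            compute_covariance(traj, "name CA")

    def test_alignment_removes_rigid_motion(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 20, (6, 3))
        frames = []
        for k in range(20):
            rot = Rotation.from_euler("z", 10 * k, degrees=True).as_matrix()
            frames.append(base @ rot.T + k * np.array([1.0, 0, 0]))
        C = compute_covariance(_traj_from_frames(frames), "name CA", align=True)
        assert np.abs(C.matrix).max() < 1e-12


class TestLinearResponse:
    def test_identity_covariance(self):
        C = CovarianceMatrix(np.eye(9), _nodes(3), 1)
        f = ForcePerturbation(1, np.array([1.0, 0, 0]))
        dR = linear_response(C, f)
        expected = np.zeros(9)
        expected[3] = 1.0
        np.testing.assert_allclose(dR.vector, expected)

    def test_scaling_covariance_scales_response_not_overlap(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((9, 9))
        C1 = CovarianceMatrix(a @ a.T, _nodes(3), 1)
        C2 = CovarianceMatrix(2 * (a @ a.T), _nodes(3), 1)
        f = ForcePerturbation(0, np.array([0.0, 1.0, 0]))
        dS = DisplacementField(rng.standard_normal(9), _nodes(3))
        r1, r2 = linear_response(C1, f), linear_response(C2, f)
        np.testing.assert_allclose(r2.vector, 2 * r1.vector)
        assert overlap(r1, dS) == pytest.approx(overlap(r2, dS))

    def test_spiked_covariance_matches_matvec_oracle(self):
        n = 6
        rng = np.random.default_rng(4)
        u = rng.standard_normal(3 * n)
        u /= np.linalg.norm(u)
        mat = 0.5 * np.eye(3 * n) + 2.0 * np.outer(u, u)
        C = CovarianceMatrix(mat, _nodes(n), 1)
        f = ForcePerturbation(4, rng.standard_normal(3))
        dR = linear_response(C, f)
        full_force = np.zeros(3 * n)
        full_force[12:15] = f.magnitude * f.direction
        np.testing.assert_allclose(dR.vector, mat @ full_force, rtol=1e-10)

    def test_index_out_of_range(self):
        C = CovarianceMatrix(np.eye(9), _nodes(3), 1)
        with pytest.raises(IllPosedError):
            linear_response(C, ForcePerturbation(3, np.array([1.0, 0, 0])))


class TestOverlap:
    def _fields(self, a, b):
        n = len(a) // 3
        return (DisplacementField(np.asarray(a, float), _nodes(n)),
                DisplacementField(np.asarray(b, float), _nodes(n)))

    def test_parallel(self):
        dR, dS = self._fields([1, 0, 0, 2, 0, 0], [1, 0, 0, 2, 0, 0])
        assert overlap(dR, dS) == pytest.approx(1.0)

    def test_orthogonal(self):
        dR, dS = self._fields([1, 0, 0, 0, 0, 0], [0, 1, 0, 0, 0, 0])
        assert overlap(dR, dS) == pytest.approx(0.0)

    def test_antiparallel_absolute_value(self):
        dR, dS = self._fields([1, 0, 0, 2, 0, 0], [-1, 0, 0, -2, 0, 0])
        assert overlap(dR, dS) == pytest.approx(1.0)

    def test_zero_response_returns_zero(self):
        dR, dS = self._fields([0, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0])
        assert overlap(dR, dS) == 0.0

    def test_zero_target_rejected(self):
        dR, dS = self._fields([1, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0])
        with pytest.raises(IllPosedError):
            overlap(dR, dS)


class TestAnalyticBestForce:
    def test_identity_covariance_formula(self):
        n = 4
        rng = np.random.default_rng(5)
        C = CovarianceMatrix(np.eye(3 * n), _nodes(n), 1)
        ds_vec = rng.standard_normal(3 * n)
        dS = DisplacementField(ds_vec, _nodes(n))
        for node in range(n):
            direction, best = analytic_best_force(C, node, dS)
            block = ds_vec[3 * node:3 * node + 3]
            np.testing.assert_allclose(
                np.abs(direction), np.abs(block / np.linalg.norm(block)), rtol=1e-9
            )
            assert best == pytest.approx(
                np.linalg.norm(block) / np.linalg.norm(ds_vec)
            )

    def test_spiked_limit_overlap_approaches_one(self):
        n, k = 8, 3
        u = np.zeros(3 * n)
        u[3 * k:3 * k + 3] = [1.0, 1.0, 1.0]
        u /= np.linalg.norm(u)
        mat = 1e-3 * np.eye(3 * n) + 1.0 * np.outer(u, u)  # lam/sigma2 = 1e3
        C = CovarianceMatrix(mat, _nodes(n), 1)
        dS = DisplacementField(u, _nodes(n))
        _, best = analytic_best_force(C, k, dS)
        assert best > 0.99

    def test_dominates_monte_carlo_direction_search(self):
        n = 6
        rng = np.random.default_rng(6)
        a = rng.standard_normal((3 * n, 3 * n))
        C = CovarianceMatrix(a @ a.T, _nodes(n), 1)
        dS = DisplacementField(rng.standard_normal(3 * n), _nodes(n))
        dirs = rng.standard_normal((100_000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for node in (0, 3, 5):
            _, best = analytic_best_force(C, node, dS)
            block = C.node_block_columns(node)
            resp = block @ dirs.T
            ov = np.abs(dS.vector @ resp) / (
                np.linalg.norm(resp, axis=0) * dS.norm
            )
            assert best >= ov.max() - 1e-12
            assert best - ov.max() < 1e-3


class TestScan:
    def test_concentrated_target_peaks_at_its_node(self):
        n, k = 5, 2
        C = CovarianceMatrix(np.eye(3 * n), _nodes(n), 1)
        ds_vec = np.zeros(3 * n)
        ds_vec[3 * k:3 * k + 3] = [1.0, -2.0, 0.5]
        dS = DisplacementField(ds_vec, _nodes(n))
        profile = scan(C, dS, n_directions=2000, n_repeats=2, seed=0)
        assert np.argmax(profile.best_overlap) == k
        assert profile.best_overlap[k] > 0.999
        # other nodes bounded by their share of the target (zero here)
        others = np.delete(profile.best_overlap, k)
        assert np.all(others < 1e-9)

    def test_never_exceeds_analytic_optimum(self):
        rng = np.random.default_rng(7)
        n = 5
        a = rng.standard_normal((3 * n, 3 * n))
        C = CovarianceMatrix(a @ a.T, _nodes(n), 1)
        dS = DisplacementField(rng.standard_normal(3 * n), _nodes(n))
        profile = scan(C, dS, n_directions=500, n_repeats=2, seed=1)
        for node in range(n):
            _, best = analytic_best_force(C, node, dS)
            assert profile.best_overlap[node] <= best + 1e-12

    def test_planted_node_recovered_from_spiked_ensemble(self):
        n, planted = 12, 4
        u = np.zeros(3 * n)
        u[3 * planted:3 * planted + 3] = 1.0
        spec = synthetic.GaussianEnsembleSpec(
            n, np.column_stack([np.arange(n) * 3.8, np.zeros(n), np.zeros(n)]),
            synthetic.Spiked(0.01, 1.0, u), 10000, 8,  # lam/sigma2 = 100
        )
        traj, _ = synthetic.generate_gaussian_ensemble(spec)
        C = compute_covariance(traj, "name CA", align=False)
        dS = DisplacementField(u, C.node_resids)
        profile = scan(C, dS, n_directions=1000, n_repeats=5, seed=2)
        assert np.argmax(profile.best_overlap) == planted

    def test_reproducible_under_seed(self):
        C = CovarianceMatrix(np.eye(12), _nodes(4), 1)
        dS = DisplacementField(np.arange(12, dtype=float), _nodes(4))
        p1 = scan(C, dS, 100, 2, seed=3)
        p2 = scan(C, dS, 100, 2, seed=3)
        np.testing.assert_array_equal(p1.best_overlap, p2.best_overlap)


class TestRankHotspots:
    def _profile(self, overlaps):
        n = len(overlaps)
        return prs.OverlapProfile(
            np.asarray(overlaps, float), np.zeros((n, 3)), _nodes(n), 100
        )

    def test_all_below_threshold(self):
        assert rank_hotspots(self._profile([0.1, 0.5, 0.59])) == []

    def test_sorted_descending_with_tie_rule(self):
        ranked = rank_hotspots(self._profile([0.7, 0.9, 0.7, 0.65]))
        assert [r[1] for r in ranked] == [2, 1, 3, 4]

    def test_inclusive_threshold(self):
        ranked = rank_hotspots(self._profile([0.6, 0.3]))
        assert len(ranked) == 1 and ranked[0][1] == 1


class TestTargetDisplacement:
    def _structure(self, coords):
        n = len(coords)
        return Structure(
            np.array(["CA"] * n), np.array(["C"] * n), np.arange(1, n + 1),
            np.array(["ALA"] * n), np.array(["A"] * n), np.asarray(coords, float),
        )

    def test_identical_structures_give_zero_field(self):
        s = self._structure(np.random.default_rng(9).uniform(0, 10, (5, 3)))
        dS = target_displacement(s, s, "name CA")
        assert dS.norm == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_gives_zero_field(self):
        coords = np.random.default_rng(10).uniform(0, 10, (6, 3))
        rot = Rotation.from_euler("y", 65, degrees=True).as_matrix()
        s1 = self._structure(coords)
        s2 = self._structure(coords @ rot.T + [3.0, 2.0, 1.0])
        dS = target_displacement(s1, s2, "name CA")
        assert dS.norm == pytest.approx(0.0, abs=1e-8)

    def test_single_node_translation_without_superposition(self):
        coords = np.column_stack([np.arange(5) * 4.0, np.zeros(5), np.zeros(5)])
        moved = coords.copy()
        moved[3, 1] += 2.0
        dS = target_displacement(
            self._structure(coords), self._structure(moved),
            "name CA", superpose=False,
        )
        expected = np.zeros(15)
        expected[10] = 2.0
        np.testing.assert_allclose(dS.vector, expected)

    def test_length_mismatch(self):
        s1 = self._structure(np.zeros((5, 3)))
        s2 = self._structure(np.zeros((4, 3)))
        with pytest.raises(SelectionError):
            target_displacement(s1, s2, "name CA")


def test_converged_start_finds_relaxation_point():
    # frames drift toward the final structure, then jitter below the bound
    rng = np.random.default_rng(11)
    final = rng.uniform(0, 20, (6, 3))
    frames = []
    for k in range(10):
        f = final + rng.normal(0, 0.01, (6, 3))
        f[0, 0] += 2.0 * max(0, 5 - k)  # internal deformation, gone by frame 5
        frames.append(f)
    traj = _traj_from_frames(frames)
    assert converged_start(traj, "name CA", rmsd_bound=0.5) == 5


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    a=st.floats(0.1, 50), b=st.floats(0.1, 50), c=st.floats(0.1, 50),
    seed=st.integers(0, 10),
)
def test_overlap_scale_invariance(a, b, c, seed):
    """Overlap is unchanged under C→aC, ΔS→bΔS, |F|→c."""
    rng = np.random.default_rng(seed)
    n = 4
    m = rng.standard_normal((3 * n, 3 * n))
    mat = m @ m.T
    nodes = _nodes(n)
    dS = rng.standard_normal(3 * n)
    direction = rng.standard_normal(3)
    f1 = ForcePerturbation(2, direction, 1.0)
    f2 = ForcePerturbation(2, direction, c)
    o1 = overlap(
        linear_response(CovarianceMatrix(mat, nodes, 1), f1),
        DisplacementField(dS, nodes),
    )
    o2 = overlap(
        linear_response(CovarianceMatrix(a * mat, nodes, 1), f2),
        DisplacementField(b * dS, nodes),
    )
    assert o1 == pytest.approx(o2, rel=1e-9)
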