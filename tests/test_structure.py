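"""Kabsch superposition, RMSD series, and greedy conformational clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import fmin
from scipy.spatial.transform import Rotation

from hyperbar import synth
from hyperbar.structure import (
    ClusterResult,
    gromos_cluster,
    kabsch_superpose,
    pairwise_rmsd_matrix,
    rmsd_series,
    round_half_away,
    summarize_clusters,
)
from hyperbar.trajio import Frame, Trajectory, select


def rotation_grid_rmsd(mobile, reference):
    """Independent oracle: minimal RMSD over a Euler-angle grid + polish."""
    mob = mobile - mobile.mean(0)
    ref = reference - reference.mean(0)

    def rmsd_of(angles):
        R = Rotation.from_euler("zyz", angles).as_matrix()
        return np.sqrt((((mob @ R.T) - ref) ** 2).sum(1).mean())

    grid = np.linspace(0, 2 * np.pi, 25, endpoint=False)
    half = np.linspace(0, np.pi, 13)
    best, best_angles = np.inf, None
    for a in grid:
        for b in half:
            for c in grid:
                v = rmsd_of((a, b, c))
                if v < best:
                    best, best_angles = v, (a, b, c)
    polished = fmin(rmsd_of, best_angles, xtol=1e-8, ftol=1e-12, disp=False)
    return min(best, rmsd_of(polished))


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd < 1e-12
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_recovers_90_degree_rotation(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        R, t, rmsd = kabsch_superpose(pts @ Rz.T, pts)
        assert rmsd < 1e-10
        np.testing.assert_allclose(R @ Rz, np.eye(3), atol=1e-8)
        assert np.isclose(np.linalg.det(R), 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_rotation_grid_oracle_on_4_point_sets(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(4, 3))
        mob = ref.copy()
        mob[seed % 4] += rng.normal(size=3) * 0.4 / np.sqrt(3)
        Rrand = Rotation.random(random_state=seed).as_matrix()
        mob = mob @ Rrand.T + rng.normal(size=3)
        _, _, rmsd = kabsch_superpose(mob, ref)
        assert abs(rmsd - rotation_grid_rmsd(mob, ref)) < 1e-3

    def test_rotation_always_proper_even_for_degenerate_sets(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        mob = ref[:, [1, 0, 2]]  # mirrored arrangement
        R, _, _ = kabsch_superpose(mob, ref)
        assert np.isclose(np.linalg.det(R), 1.0)

    def test_weight_validation(self):
        pts = np.zeros((4, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(pts, pts, weights=np.zeros(4))


class TestRmsdSeries:
    def test_identical_frames_all_zero(self, small_system):
        top, traj = small_system
        sub = Trajectory(top, [Frame(i * 2.0, traj.frames[0].coordinates.copy(),
                                     traj.frames[0].box) for i in range(4)])
        protein = select(top, name="CA")
        s = rmsd_series(sub, protein)
        np.testing.assert_allclose(s.values, 0.0, atol=1e-10)

    def test_rigid_rotations_of_frame0_all_zero(self, small_system):
        top, traj = small_system
        base = traj.frames[0].coordinates
        frames = []
        for i in range(4):
            R = Rotation.from_euler("xyz", [10 * i, 5 * i, -7 * i],
                                    degrees=True).as_matrix()
            frames.append(Frame(2.0 * i, base @ R.T + i * 0.3, traj.frames[0].box))
        protein = select(top, name="CA")
        s = rmsd_series(Trajectory(top, frames), protein)
        np.testing.assert_allclose(s.values, 0.0, atol=1e-9)
        assert s.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_growing_gaussian_noise_matches_analytic_mean(self, small_system):
        # E[RMSD] for N(0, sigma^2) iid displacement over N atoms is
        # ~ sigma*sqrt(3) for large N (superposition removes ~6 DOF)
        top, traj = small_system
        rng = np.random.default_rng(42)
        base = traj.frames[0].coordinates
        sigmas = 0.05 * np.arange(1, 7)
        frames = [Frame(0.0, base.copy(), traj.frames[0].box)]
        for i, s in enumerate(sigmas):
            frames.append(Frame(2.0 * (i + 1), base + rng.normal(0, s, base.shape),
                                traj.frames[0].box))
        protein = select(top, name="CA")
        n = len(protein)
        series = rmsd_series(Trajectory(top, frames), protein)
        assert np.all(np.diff(series.values) > 0)  # grows with sigma
        expected = sigmas * np.sqrt(3.0 * (1 - 2.0 / n))
        # single-frame values fluctuate; the mean ratio over frames is tight
        assert np.mean(series.values[1:] / expected) == pytest.approx(1.0,
                                                                      abs=0.05)


def brute_force_gromos(D, cutoff):
    """Independent greedy oracle (set-based, no vectorisation)."""
    n = len(D)
    pool = set(range(n))
    clusters = []
    while pool:
        counts = {
            i: sum(1 for j in pool if D[i][j] <= cutoff) for i in pool
        }
        best = min(pool, key=lambda i: (-counts[i], i))
        members = sorted(j for j in pool if D[best][j] <= cutoff)
        clusters.append((best, members))
        pool -= set(members)
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return clusters


class TestGromosCluster:
    def test_all_zero_distances_one_cluster(self):
        res = gromos_cluster(np.zeros((5, 5)), 0.5)
        assert res.n_clusters == 1
        assert res.probabilities[0] == 1.0

    def test_three_frame_example(self):
        D = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        res = gromos_cluster(D, 0.5)
        assert list(res.cluster_sizes) == [2, 1]
        assert res.assignments[0] == res.assignments[1] != res.assignments[2]
        assert res.centroids[0] in (0, 1)

    def test_two_tight_triplets(self):
        pts = np.array([0.0, 0.01, 0.02, 2.0, 2.01, 2.02])
        D = np.abs(pts[:, None] - pts[None, :])
        res = gromos_cluster(D, 0.5)
        assert list(res.cluster_sizes) == [3, 3]
        oracle = brute_force_gromos(D, 0.5)
        assert [len(m) for _, m in oracle] == [3, 3]
        assert [c for c, _ in oracle] == list(res.centroids)

    @given(st.integers(0, 200))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle_on_small_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 9)
        # distances drawn from a fixed grid to exercise ties
        vals = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=(n, n))
        D = np.triu(vals, 1)
        D = D + D.T
        res = gromos_cluster(D, 0.5)
        oracle = brute_force_gromos(D, 0.5)
        assert list(res.centroids) == [c for c, _ in oracle]
        for cid, (_, members) in enumerate(oracle):
            assert sorted(np.nonzero(res.assignments == cid)[0]) == members
        assert res.cluster_sizes.sum() == n

    def test_cutoff_extremes(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 1, 6)
        D = np.abs(pts[:, None] - pts[None, :])
        assert gromos_cluster(D, D.max() + 1).n_clusters == 1
        tiny = D[D > 0].min() / 2
        assert gromos_cluster(D, tiny).n_clusters == 6

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            gromos_cluster(D, 0.5)


class TestSummarize:
    @pytest.mark.parametrize("total,biggest,n_clusters,expected", [
        (14251, 11872, 11, 0.83),
        (12751, 3812, 31, 0.30),
        (13501, 2812, 30, 0.21),
    ])
    def test_biggest_cluster_probability_from_frame_counts(
        self, total, biggest, n_clusters, expected
    ):
        rest = total - biggest
        sizes = [biggest]
        per = rest // (n_clusters - 1)
        sizes += [per] * (n_clusters - 2)
        sizes.append(rest - per * (n_clusters - 2))
        sizes = sorted(sizes, reverse=True)
        assignments = np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])
        centroids = np.cumsum([0] + sizes[:-1])
        res = ClusterResult(assignments, np.array(sizes), centroids, 0.5)
        summary = summarize_clusters(res, np.arange(total) * 2.0)
        assert summary["biggest_probability"] == pytest.approx(expected)
        assert summary["total_frames"] == total
        assert summary["n_clusters"] == n_clusters

    def test_single_frame(self):
        res = ClusterResult(np.array([0]), np.array([1]), np.array([0]), 0.5)
        s = summarize_clusters(res, np.array([42.0]))
        assert s["biggest_probability"] == 1.0
        assert s["biggest_first_ps"] == s["biggest_middle_ps"] == \
               s["biggest_last_ps"] == 42.0

    def test_middle_is_ordinal_ceil_k_over_2(self):
        res = ClusterResult(np.zeros(4, int), np.array([4]), np.array([0]), 0.5)
        s = summarize_clusters(res, np.array([10.0, 20.0, 30.0, 40.0]))
        assert s["biggest_middle_ps"] == 20.0

    def test_round_half_away(self):
        assert round_half_away(0.835, 2) == 0.84
        assert round_half_away(-0.615, 2) == -0.62
        assert round_half_away(0.29896, 2) == 0.30


class TestPairwiseMatrix:
    def test_symmetric_zero_diagonal_and_rigid_invariance(self, small_system):
        top, traj = small_system
        protein = select(top, name="CA")
        idx = np.arange(4)
        mat = pairwise_rmsd_matrix(traj, protein, idx)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)
        # rotating every frame rigidly must not change the matrix
        rot_frames = []
        for i, fi in enumerate(idx):
            R = Rotation.from_euler("z", 30 * i, degrees=True).as_matrix()
            fr = traj.frames[fi]
            rot_frames.append(Frame(fr.time, fr.coordinates @ R.T, fr.box))
        mat2 = pairwise_rmsd_matrix(Trajectory(top, rot_frames), protein)
        np.testing.assert_allclose(mat2, mat, atol=1e-9)
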