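"""Superposition, RMSD/RMSF, PCA and free-energy landscapes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from foldscape import md
from foldscape.md import Trajectory, fel, pca, porcupine, rmsd_series, rmsf_profile, superpose
from foldscape.synthetic import (
    TrajectoryTruth,
    gen_trajectory,
    project_internal,
    random_internal_modes,
)


@pytest.fixture(scope="module")
def single_mode_traj():
    rng = np.random.default_rng(10)
    mean = rng.uniform(-10, 10, (15, 3))
    modes = random_internal_modes(mean, 1, seed=10)
    truth = TrajectoryTruth(mean, modes, [2.0], 2000, seed=10)
    return gen_trajectory(truth), truth


@pytest.fixture(scope="module")
def two_basin_traj():
    rng = np.random.default_rng(20)
    mean = rng.uniform(-10, 10, (15, 3))
    modes = random_internal_modes(mean, 2, seed=20)
    truth = TrajectoryTruth(
        mean, modes, [0.5, 0.5], 10000,
        basin_centers=[[-3.0, 0.0], [3.0, 0.0]], basin_weights=[0.7, 0.3], seed=20,
    )
    return gen_trajectory(truth), truth


class TestSuperpose:
    def test_identical_structures(self):
        ref = np.random.default_rng(0).uniform(-5, 5, (10, 3))
        _, r = superpose(ref, ref)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self):
        ref = np.random.default_rng(1).uniform(-5, 5, (10, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = ref @ rot.T + np.array([3.0, -1.0, 2.0])
        _, r = superpose(moved, ref)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_invariant_under_proper_rigid_motion(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(-5, 5, (12, 3))
        mob = ref + rng.normal(0, 0.3, (12, 3))
        _, r0 = superpose(mob, ref)
        rot = Rotation.from_euler("xyz", [17, -40, 111], degrees=True).as_matrix()
        _, r1 = superpose(mob @ rot.T + 5.0, ref)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_three_atom_displacement_against_rotation_grid_oracle(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        mob = np.array([[0.3, 0.0, 0], [1, 0, 0], [0, 1, 0]])
        _, r = superpose(mob, ref)
        # brute force: exhaustive search over rotations (Euler grid) and the
        # optimal translation (centroid match)
        best = np.inf
        mc = mob - mob.mean(axis=0)
        rc = ref - ref.mean(axis=0)
        grid = np.arange(-15.0, 15.0, 0.25)
        for a in grid:
            for b in grid[::4]:
                for c in grid[::4]:
                    rot = Rotation.from_euler("xyz", [a, b, c], degrees=True).as_matrix()
                    d = mc @ rot.T - rc
                    best = min(best, np.sqrt(np.mean(np.sum(d * d, axis=1))))
        assert r <= best + 1e-9
        assert r == pytest.approx(best, abs=1e-3)

    def test_collinear_geometry_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            superpose(line, line + 1.0)


class TestRMSD:
    def test_self_trajectory_is_zero(self):
        ref = np.random.default_rng(3).uniform(-5, 5, (8, 3))
        traj = Trajectory(np.stack([ref] * 5))
        np.testing.assert_allclose(rmsd_series(traj, ref), 0.0, atol=1e-12)

    @staticmethod
    def _deep_valley(values, bins):
        """True when the histogram shows two peaks split by a deep valley."""
        from scipy.signal import find_peaks

        counts, _ = np.histogram(values, bins=bins)
        smooth = np.convolve(counts, np.ones(3) / 3, mode="same")
        peaks, _ = find_peaks(smooth, height=0.15 * smooth.max(), distance=3)
        if len(peaks) < 2:
            return False
        top2 = peaks[np.argsort(smooth[peaks])[-2:]]
        lo, hi = sorted(top2)
        valley = smooth[lo:hi + 1].min()
        return valley < 0.5 * min(smooth[lo], smooth[hi])

    def test_two_basin_trajectory_has_bimodal_rmsd(self, two_basin_traj):
        traj, _ = two_basin_traj
        r = rmsd_series(traj, traj.coordinates[0])
        assert self._deep_valley(r, bins=40)

    def test_single_basin_trajectory_unimodal(self, single_mode_traj):
        traj, _ = single_mode_traj
        r = rmsd_series(traj, traj.coordinates[0])
        assert not self._deep_valley(r, bins=40)


class TestRMSF:
    def test_frozen_trajectory_is_zero(self):
        ref = np.random.default_rng(4).uniform(-5, 5, (8, 3))
        traj = Trajectory(np.stack([ref] * 6))
        np.testing.assert_allclose(rmsf_profile(traj), 0.0, atol=1e-12)

    def test_localized_mode_shows_on_the_right_atom(self):
        rng = np.random.default_rng(5)
        mean = rng.uniform(-10, 10, (20, 3))
        raw = np.zeros(60)
        raw[3 * 4] = 1.0  # x of atom 4; rigid-body part removed below
        mode = project_internal(raw[None, :], mean)
        truth = TrajectoryTruth(mean, mode, [1.5], 2000, seed=5)
        traj = gen_trajectory(truth)
        rmsf = rmsf_profile(traj)
        per_atom = 1.5 * np.linalg.norm(mode.reshape(20, 3), axis=1)
        assert rmsf[4] == pytest.approx(per_atom[4], rel=0.15)
        assert np.argmax(rmsf) == 4
        others = np.delete(rmsf, 4)
        assert np.all(others < 0.5 * rmsf[4])

    def test_rmsf_squared_sum_equals_eigenvalue_sum(self, single_mode_traj):
        traj, _ = single_mode_traj
        rmsf = rmsf_profile(traj)
        res = pca(traj)
        assert np.sum(rmsf**2) == pytest.approx(np.sum(res.eigenvalues), rel=1e-6)


class TestPCA:
    def test_recovers_generating_mode(self, single_mode_traj):
        traj, truth = single_mode_traj
        res = pca(traj)
        assert abs(res.eigenvectors[0] @ truth.mode_vectors[0]) > 0.99
        assert res.eigenvalues[0] == pytest.approx(4.0, rel=0.15)

    def test_eigenvalue_sum_equals_total_variance(self, two_basin_traj):
        traj, _ = two_basin_traj
        res = pca(traj)
        frames, mean = md.align_trajectory(traj)
        x = frames.reshape(traj.n_frames, -1) - mean.reshape(-1)
        assert np.sum(res.eigenvalues) == pytest.approx(
            np.sum(x * x) / traj.n_frames, rel=1e-6
        )

    def test_covariance_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(0, 1, (40, 5, 3)) + rng.uniform(-5, 5, (1, 5, 3))
        traj = Trajectory(coords)
        frames, mean = md.align_trajectory(traj)
        x = frames.reshape(40, 15)
        mu = x.mean(axis=0)
        n3 = 15
        cov_naive = np.empty((n3, n3))
        for i in range(n3):
            for j in range(n3):
                cov_naive[i, j] = np.mean((x[:, i] - mu[i]) * (x[:, j] - mu[j]))
        evals_naive = np.sort(np.linalg.eigvalsh(cov_naive))[::-1]
        res = pca(traj)
        # align_trajectory subtracts the refined mean, not the post-alignment
        # column mean; the two agree after convergence
        np.testing.assert_allclose(res.eigenvalues, np.clip(evals_naive, 0, None),
                                   atol=1e-10)

    def test_eigenvectors_orthonormal_and_reconstruction_exact(self, two_basin_traj):
        traj, _ = two_basin_traj
        res = pca(traj)
        gram = res.eigenvectors @ res.eigenvectors.T
        np.testing.assert_allclose(gram, np.eye(len(res.eigenvalues)), atol=1e-8)
        frames, mean = md.align_trajectory(traj)
        x = frames.reshape(traj.n_frames, -1) - mean.reshape(-1)
        recon = res.projections @ res.eigenvectors
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_rank_deficiency_warns(self):
        rng = np.random.default_rng(7)
        traj = Trajectory(rng.normal(0, 1, (5, 10, 3)))
        with pytest.warns(RuntimeWarning):
            pca(traj)


class TestFEL:
    def test_most_populated_bin_is_zero_and_occupied_nonnegative(self, two_basin_traj):
        traj, _ = two_basin_traj
        res = pca(traj, 2)
        grid = fel(res.projections[:, :2], bins=30)
        occ = grid.free_energy[~grid.mask]
        assert occ.min() == 0.0
        assert np.all(occ >= 0)
        assert np.all(np.isnan(grid.free_energy[grid.mask]))

    def test_uniform_projections_give_flat_landscape(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, (20000, 2))
        grid = fel(p, bins=5)
        occ = grid.free_energy[~grid.mask]
        assert occ.max() < 0.15  # flat within counting noise

    def test_population_ratio_gives_boltzmann_gap(self, two_basin_traj):
        traj, _ = two_basin_traj
        res = pca(traj, 2)
        grid = fel(res.projections[:, :2], bins=30)
        # deepest bin in each half-plane along PC1
        centers = 0.5 * (grid.pc1_edges[:-1] + grid.pc1_edges[1:])
        g = np.where(grid.mask, np.inf, np.nan_to_num(grid.free_energy, nan=np.inf))
        left = g[centers < 0].min()
        right = g[centers > 0].min()
        assert abs(left - right) == pytest.approx(np.log(7.0 / 3.0), rel=0.10)

    def test_uniform_count_smoothing_lowers_energies(self, two_basin_traj):
        # adding a constant count to every bin compresses the landscape
        traj, _ = two_basin_traj
        res = pca(traj, 2)
        p = res.projections[:, :2]
        counts, e1, e2 = np.histogram2d(p[:, 0], p[:, 1], bins=20)
        g_raw = -np.log(counts / counts.max(), where=counts > 0,
                        out=np.full_like(counts, np.nan))
        counts_s = counts + 5.0
        g_s = -np.log(counts_s / counts_s.max())
        occ = counts > 0
        assert np.all(g_s[occ] <= g_raw[occ] + 1e-12)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            fel(np.zeros((50, 2)))


class TestPorcupine:
    def test_vectors_parallel_to_generating_mode(self, single_mode_traj):
        traj, truth = single_mode_traj
        res = pca(traj, 1)
        field = porcupine(res, 0)
        v = field.vectors.reshape(-1)
        cos = abs(v @ truth.mode_vectors[0]) / np.linalg.norm(v)
        assert cos > 0.99

    def test_zero_variance_component_gives_zero_vectors(self):
        ref = np.random.default_rng(9).uniform(-5, 5, (8, 3))
        traj = Trajectory(np.stack([ref] * 20))
        res = pca(traj, 2)
        field = porcupine(res, 1)
        np.testing.assert_allclose(field.vectors, 0.0, atol=1e-9)

    def test_norm_scales_with_projection_range(self, single_mode_traj):
        traj, _ = single_mode_traj
        res = pca(traj, 1)
        field = porcupine(res, 0)
        rng_span = res.projections[:, 0].max() - res.projections[:, 0].min()
        assert np.linalg.norm(field.vectors) == pytest.approx(rng_span, rel=1e-9)
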