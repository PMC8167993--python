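import itertools

import numpy as np
import pytest

from mkldbp.mkl_cka import (
    alignment,
    build_problem,
    center_kernel,
    centered_alignment,
    combine_kernels,
    mean_weights,
    solve_weights,
)


def random_psd(rng, n):
    A = rng.normal(size=(n, n))
    return A @ A.T / n


def random_rbf(rng, n, d=4, gamma=1.0):
    X = rng.uniform(size=(n, d))
    sq = ((X[:, None] - X[None, :]) ** 2).sum(-1)
    return np.exp(-gamma * sq)


def simplex_grid(m, step):
    """All weight vectors on the simplex with coordinates in multiples of step."""
    k = round(1.0 / step)
    for parts in itertools.product(range(k + 1), repeat=m - 1):
        if sum(parts) <= k:
            yield np.array(list(parts) + [k - sum(parts)]) * step


def grid_objective(problem, step=0.02):
    Q = problem.M + problem.lam * problem.L
    best = np.inf
    for b in simplex_grid(problem.m, step):
        best = min(best, float(b @ Q @ b - 2 * problem.a @ b))
    return best


def balanced_labels(n):
    return np.array([1, -1] * (n // 2))


class TestCentering:
    def test_row_and_column_sums_zero(self):
        rng = np.random.default_rng(0)
        for seed in range(50):
            K = random_psd(np.random.default_rng(seed), 12)
            Kc = center_kernel(K)
            assert np.abs(Kc.sum(axis=0)).max() < 1e-8
            assert np.abs(Kc.sum(axis=1)).max() < 1e-8

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        K = random_psd(rng, 15)
        once = center_kernel(K)
        np.testing.assert_allclose(center_kernel(once), once, atol=1e-10)

    def test_all_ones_annihilated(self):
        np.testing.assert_allclose(center_kernel(np.ones((8, 8))), 0.0,
                                   atol=1e-12)

    def test_matches_dense_centering_matrix(self):
        rng = np.random.default_rng(2)
        n = 9
        K = random_psd(rng, n)
        U = np.eye(n) - np.ones((n, n)) / n
        np.testing.assert_allclose(center_kernel(K), U @ K @ U, atol=1e-10)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            center_kernel(np.ones((3, 4)))


class TestAlignment:
    def test_self_alignment_is_one(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(6, 6))
        assert alignment(P, P) == pytest.approx(1.0, abs=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        P, Q = rng.normal(size=(2, 5, 5))
        assert alignment(3.7 * P, Q) == pytest.approx(alignment(P, Q), abs=1e-10)

    def test_identity_vs_ones_closed_form(self):
        val = alignment(np.eye(2), np.ones((2, 2)))
        assert val == pytest.approx(1 / np.sqrt(2), abs=1e-10)

    def test_bounded_by_one(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            P, Q = rng.normal(size=(2, 7, 7))
            assert abs(alignment(P, Q)) <= 1 + 1e-10

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            alignment(np.zeros((3, 3)), np.eye(3))


class TestCenteredAlignment:
    def test_ideal_kernel_scores_one(self):
        y = balanced_labels(8)
        K = np.outer(y, y).astype(float)
        # y y^T is already centered for balanced labels
        assert centered_alignment(K, y) == pytest.approx(1.0, abs=1e-10)

    def test_all_ones_kernel_rejected(self):
        y = balanced_labels(6)
        with pytest.raises(ValueError, match="centers to zero"):
            centered_alignment(np.ones((6, 6)), y)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(5)
        n = 8
        y = balanced_labels(n)
        K = random_psd(rng, n)
        U = np.eye(n) - np.ones((n, n)) / n
        Kc = U @ K @ U
        expected = np.sum(Kc * np.outer(y, y)) / (
            np.linalg.norm(Kc) * np.linalg.norm(np.outer(y, y))
        )
        assert centered_alignment(K, y) == pytest.approx(expected, abs=1e-10)

    def test_bad_labels_rejected(self):
        K = np.eye(4)
        with pytest.raises(ValueError, match="labels"):
            centered_alignment(K, np.array([1, 0, 1, -1]))


class TestBuildProblem:
    def test_identical_kernels_structure(self):
        rng = np.random.default_rng(6)
        K = random_rbf(rng, 10)
        y = balanced_labels(10)
        p = build_problem([K, K, K], y, lam=0.5)
        assert np.ptp(p.M) < 1e-8 * np.abs(p.M).max()
        np.testing.assert_allclose(p.W, 1.0, atol=1e-10)
        np.testing.assert_allclose(p.L.sum(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(p.L, 3 * np.eye(3) - np.ones((3, 3)),
                                   atol=1e-10)

    def test_small_problem_matches_dense_oracle(self):
        # m = 2, N = 4: every quantity recomputed with the materialized
        # centering matrix and explicit Frobenius sums.
        K1 = np.array([[1.0, 0.5, 0.2, 0.1],
                       [0.5, 1.0, 0.3, 0.2],
                       [0.2, 0.3, 1.0, 0.4],
                       [0.1, 0.2, 0.4, 1.0]])
        K2 = np.array([[1.0, 0.9, 0.1, 0.0],
                       [0.9, 1.0, 0.2, 0.1],
                       [0.1, 0.2, 1.0, 0.8],
                       [0.0, 0.1, 0.8, 1.0]])
        y = np.array([1, 1, -1, -1])
        U = np.eye(4) - np.ones((4, 4)) / 4
        C1, C2 = U @ K1 @ U, U @ K2 @ U
        yy = np.outer(y, y)
        p = build_problem([K1, K2], y, lam=0.8)
        np.testing.assert_allclose(
            p.a, [np.sum(C1 * yy), np.sum(C2 * yy)], atol=1e-10
        )
        expected_M = [[np.sum(C1 * C1), np.sum(C1 * C2)],
                      [np.sum(C2 * C1), np.sum(C2 * C2)]]
        np.testing.assert_allclose(p.M, expected_M, atol=1e-10)
        w12 = np.sum(K1 * K2) / (np.linalg.norm(K1) * np.linalg.norm(K2))
        np.testing.assert_allclose(p.W, [[1.0, w12], [w12, 1.0]], atol=1e-10)
        np.testing.assert_allclose(p.L, p.D - p.W, atol=1e-12)

    def test_M_is_psd(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            Ks = [random_rbf(rng, 12, gamma=g) for g in (0.2, 1.0, 3.0)]
            p = build_problem(Ks, balanced_labels(12), lam=0.0)
            assert np.linalg.eigvalsh(p.M).min() >= -1e-8 * np.abs(p.M).max()

    def test_laplacian_psd_with_zero_row_sums(self):
        rng = np.random.default_rng(7)
        Ks = [random_rbf(rng, 10, gamma=g) for g in (0.5, 1.0, 2.0, 4.0)]
        p = build_problem(Ks, balanced_labels(10), lam=1.0)
        assert np.linalg.eigvalsh(p.L).min() >= -1e-10
        np.testing.assert_allclose(p.L.sum(axis=1), 0.0, atol=1e-10)


class TestSolveWeights:
    def test_identical_kernels_give_uniform_weights(self):
        rng = np.random.default_rng(8)
        K = random_rbf(rng, 10)
        y = balanced_labels(10)
        for lam in (0.0, 0.8, 100.0):
            sol = solve_weights(build_problem([K] * 4, y, lam=lam))
            np.testing.assert_allclose(sol.beta, 0.25, atol=1e-6)

    def test_objective_matches_grid_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Ks = [random_rbf(rng, 30, gamma=g)
                  for g in rng.uniform(0.1, 3.0, size=3)]
            p = build_problem(Ks, balanced_labels(30), lam=0.8)
            sol = solve_weights(p)
            grid_best = grid_objective(p, step=0.02)
            scale = max(abs(grid_best), 1.0)
            assert sol.objective <= grid_best + 1e-3 * scale

    def test_feasibility(self):
        for seed in range(10):
            rng = np.random.default_rng(seed + 100)
            Ks = [random_rbf(rng, 16, gamma=g) for g in (0.2, 1.0, 5.0)]
            sol = solve_weights(build_problem(Ks, balanced_labels(16), lam=0.8))
            assert sol.beta.min() >= 0.0
            assert sol.beta.sum() == pytest.approx(1.0, abs=1e-8)

    def test_smoothing_pulls_weights_uniform(self):
        rng = np.random.default_rng(9)
        Ks = [random_rbf(rng, 20, gamma=g) for g in (0.1, 0.5, 2.0)]
        y = balanced_labels(20)
        variances = []
        for lam in (0.0, 0.8, 10.0, 100.0, 1e6):
            beta = solve_weights(build_problem(Ks, y, lam=lam)).beta
            variances.append(beta.var())
        assert all(b <= a + 1e-12 for a, b in zip(variances, variances[1:]))
        final = solve_weights(build_problem(Ks, y, lam=1e6)).beta
        assert np.abs(final - 1 / 3).max() < 0.01

    def test_informative_kernel_wins(self):
        # K1 built from label-informative features, K2/K3 from pure noise.
        rng = np.random.default_rng(10)
        n = 60
        y = balanced_labels(n)
        informative = y[:, None] * 0.5 + rng.normal(0, 0.1, size=(n, 5))
        K1 = np.exp(-((informative[:, None] - informative[None, :]) ** 2).sum(-1))
        Ks = [K1] + [random_rbf(np.random.default_rng(s), n, d=5)
                     for s in (11, 12)]
        beta = solve_weights(build_problem(Ks, y, lam=0.8)).beta
        assert beta[0] > max(beta[1], beta[2])


class TestCombine:
    def test_one_hot_returns_that_kernel(self):
        rng = np.random.default_rng(13)
        Ks = [random_rbf(rng, 8) for _ in range(3)]
        np.testing.assert_array_equal(
            combine_kernels(Ks, np.array([0.0, 1.0, 0.0])), Ks[1]
        )

    def test_uniform_over_identical_kernels(self):
        rng = np.random.default_rng(14)
        K = random_rbf(rng, 8)
        np.testing.assert_allclose(
            combine_kernels([K, K, K], mean_weights(3)), K, atol=1e-12
        )

    def test_convex_combination_stays_psd(self):
        rng = np.random.default_rng(15)
        Ks = [random_rbf(rng, 10, gamma=g) for g in (0.3, 1.0, 3.0)]
        beta = np.array([0.2, 0.5, 0.3])
        assert np.linalg.eigvalsh(combine_kernels(Ks, beta)).min() >= -1e-8

    def test_off_simplex_weights_rejected(self):
        rng = np.random.default_rng(16)
        Ks = [random_rbf(rng, 5) for _ in range(2)]
        with pytest.raises(ValueError, match="simplex"):
            combine_kernels(Ks, np.array([0.7, 0.7]))
        with pytest.raises(ValueError, match="weights"):
            combine_kernels(Ks, np.array([1.0]))
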