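import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kcselect import (
    DegenerateGeometryError,
    ParameterError,
    gaussian_kernel,
    kernel_bank,
    local_scales,
    nmi,
    simlr_similarity,
    single_kernel_similarity,
)
from kcselect.similarity import (
    kernel_pseudo_distances,
    project_rows_to_simplex,
)

from conftest import make_blobs

COLLINEAR = np.array([[0.0], [1.0], [3.0]])


class TestLocalScales:
    def test_one_neighbor_hand_enumeration(self):
        np.testing.assert_allclose(local_scales(COLLINEAR, 1), [1.0, 1.0, 2.0])

    def test_two_neighbor_means(self):
        np.testing.assert_allclose(local_scales(COLLINEAR, 2), [2.0, 1.5, 2.5])

    def test_duplicates_give_zero_scale(self):
        sig = local_scales(np.array([[0.0], [0.0], [5.0]]), 1)
        assert sig[0] == 0.0 and sig[1] == 0.0

    def test_k_out_of_range(self):
        with pytest.raises(ParameterError):
            local_scales(COLLINEAR, 3)


class TestGaussianKernel:
    def test_diagonal_value(self):
        # at zero distance with sigma_i = 1, sigma = 1: 1 / (2 sqrt(2 pi))
        K = gaussian_kernel(COLLINEAR, 1, 1.0)
        assert K.values[0, 0] == pytest.approx(1.0 / (2.0 * np.sqrt(2 * np.pi)))

    def test_two_point_off_diagonal(self):
        # distance 1, sigma_1 = sigma_2 = 1 -> exp(-1/2) / (2 sqrt(2 pi))
        K = gaussian_kernel(COLLINEAR, 1, 1.0)
        assert K.values[0, 1] == pytest.approx(
            np.exp(-0.5) / (2.0 * np.sqrt(2 * np.pi))
        )

    def test_symmetry(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        K = gaussian_kernel(X, 3, 1.5).values
        np.testing.assert_allclose(K, K.T, atol=0)

    def test_duplicate_pair_raises_by_default(self):
        X = np.vstack([np.zeros((3, 2)), np.ones((3, 2))])
        with pytest.raises(DegenerateGeometryError, match="zero"):
            gaussian_kernel(X, 2, 1.0)
        # the floor policy survives duplicates as long as some scale is positive
        X2 = np.vstack([X, [[5.0, 5.0]]])
        K = gaussian_kernel(X2, 2, 1.0, zero_scale="floor")
        assert np.all(np.isfinite(K.values))
        # identical-everything geometry stays an error even under the floor
        with pytest.raises(DegenerateGeometryError):
            gaussian_kernel(np.zeros((5, 2)), 2, 1.0, zero_scale="floor")


class TestKernelBank:
    def test_full_grids_give_55_kernels(self):
        X = np.random.default_rng(1).normal(size=(40, 6))
        assert len(kernel_bank(X)) == 55

    def test_truncated_grid_at_n_25(self):
        X = np.random.default_rng(2).normal(size=(25, 6))
        with pytest.warns(UserWarning, match="truncated"):
            bank = kernel_bank(X)
        assert len(bank) == 40  # k in {10,...,24} (8 values) × 5 sigmas

    def test_singleton_grids(self):
        X = np.random.default_rng(3).normal(size=(20, 4))
        assert len(kernel_bank(X, k_grid=(5,), sigma_grid=(1.0,))) == 1

    def test_pseudo_distances_nonnegative(self):
        X = np.random.default_rng(4).normal(size=(35, 5))
        D = kernel_pseudo_distances(kernel_bank(X))
        assert D.min() >= -1e-10


class TestSingleKernelSimilarity:
    def test_rows_sum_to_one(self):
        X = np.random.default_rng(5).normal(size=(30, 8))
        S = single_kernel_similarity(X)
        np.testing.assert_allclose(S.values.sum(axis=1), 1.0, atol=1e-8)
        assert S.mode == "G"

    def test_within_cluster_dominates(self):
        # two tight clusters far apart: within-block similarity ≫ between
        X = np.vstack([np.random.default_rng(6).normal(0, 0.1, (3, 2)),
                       np.random.default_rng(7).normal(50, 0.1, (3, 2))])
        S = single_kernel_similarity(X, k=2).values
        within = (S[:3, :3].sum() + S[3:, 3:].sum() - np.trace(S)) / 12
        between = S[:3, 3:].mean()
        assert within > 100 * between

    def test_permutation_equivariance(self):
        X = np.random.default_rng(8).normal(size=(20, 5))
        perm = np.random.default_rng(9).permutation(20)
        S1 = single_kernel_similarity(X).values
        S2 = single_kernel_similarity(X[perm]).values
        np.testing.assert_allclose(S2, S1[np.ix_(perm, perm)], atol=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_simplex_projection_is_valid_and_idempotent(seed):
    U = np.random.default_rng(seed).normal(scale=3.0, size=(4, 6))
    P = project_rows_to_simplex(U)
    assert P.min() >= 0
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
    np.testing.assert_allclose(project_rows_to_simplex(P), P, atol=1e-10)


class TestSimlr:
    @pytest.fixture(scope="class")
    def state30(self):
        X = np.random.default_rng(10).normal(size=(30, 10))
        with pytest.warns(UserWarning, match="truncated"):
            return simlr_similarity(X, C=3)

    def test_objective_non_increasing(self, state30):
        obj = state30.objective
        assert np.all(np.diff(obj) <= 1e-6 * np.abs(obj[:-1]) + 1e-12)

    def test_row_stochastic_every_iteration(self, state30):
        assert state30.row_sum_dev.max() <= 1e-8
        S = state30.S.values
        assert S.min() >= 0

    def test_weights_on_simplex_every_iteration(self, state30):
        assert state30.simplex_dev.max() <= 1e-10
        np.testing.assert_allclose(state30.w.sum(), 1.0, atol=1e-10)
        assert state30.w.min() >= 0

    def test_latent_factor_orthonormal(self, state30):
        L = state30.L
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_large_rho_gives_uniform_weights(self):
        X, _ = make_blobs((0, 5, 10), per=12, seed=11)
        st_ = simlr_similarity(X, C=3, rho=1e9)
        assert np.abs(st_.w - 1.0 / st_.w.size).max() < 1e-3

    def test_blob_recovery_by_spectral_clustering(self):
        from sklearn.cluster import SpectralClustering

        X, truth = make_blobs((0, 5, 10), per=15, seed=12)
        st_ = simlr_similarity(X, C=3)
        A = 0.5 * (st_.S.values + st_.S.values.T)
        pred = SpectralClustering(
            3, affinity="precomputed", random_state=0
        ).fit_predict(A)
        assert nmi(pred + 1, truth) == pytest.approx(1.0)
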