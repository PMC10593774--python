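import math

import numpy as np
import pytest

from conftest import naive_snf, random_affinity
from fusemap.datatypes import AffinityMatrix
from fusemap.fusion import (
    SNFParams,
    full_kernel,
    pairwise_sq_euclidean,
    scaled_exp_kernel,
    snf_fuse,
    sparse_kernel,
)


class TestPairwiseSqEuclidean:
    def test_hand_values(self):
        D = pairwise_sq_euclidean(np.array([[0.0], [3.0]]))
        assert np.allclose(D, [[0, 9], [9, 0]])

    def test_identical_rows_zero(self, rng):
        X = rng.normal(size=(4, 3))
        X[2] = X[0]
        D = pairwise_sq_euclidean(X)
        assert D[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce(self, rng):
        X = rng.normal(size=(5, 3))
        D = pairwise_sq_euclidean(X)
        brute = [[sum((X[i, k] - X[j, k]) ** 2 for k in range(3)) for j in range(5)] for i in range(5)]
        assert np.allclose(D, brute, atol=1e-12)

    def test_rejects_nonfinite(self):
        X = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="non-finite"):
            pairwise_sq_euclidean(X, subject_ids=["a", "b"])


def scalar_kernel_oracle(D, K, mu):
    """Independent scalar implementation of the scaled exponential kernel."""
    n = D.shape[0]
    W = np.zeros_like(D)
    means = []
    for i in range(n):
        dists = sorted(D[i, j] for j in range(n) if j != i)
        means.append(sum(dists[:K]) / K)
    for i in range(n):
        for j in range(n):
            eps = (means[i] + means[j] + D[i, j]) / 3.0
            W[i, j] = math.exp(-D[i, j] / (mu * eps))
    return (W + W.T) / 2.0


class TestScaledExpKernel:
    def test_zero_distance_gives_unit_affinity(self, rng):
        X = rng.normal(size=(5, 2))
        X[1] = X[0]
        D = pairwise_sq_euclidean(X)
        # before symmetrization both directions are exp(0) = 1 already
        W = scaled_exp_kernel(D, SNFParams(K=2, mu=0.8))
        assert W[0, 1] == pytest.approx(1.0)

    def test_matches_scalar_oracle_on_toy(self, rng):
        X = rng.normal(size=(4, 3))
        D = pairwise_sq_euclidean(X)
        W = scaled_exp_kernel(D, SNFParams(K=2, mu=0.8))
        assert np.allclose(W, scalar_kernel_oracle(D, 2, 0.8), atol=1e-12)

    def test_feature_scale_invariance(self, rng):
        X = rng.normal(size=(8, 4))
        p = SNFParams(K=3, mu=0.8)
        W1 = scaled_exp_kernel(pairwise_sq_euclidean(X), p)
        W2 = scaled_exp_kernel(pairwise_sq_euclidean(3.7 * X), p)
        assert np.allclose(W1, W2, atol=1e-10)

    def test_monotone_in_distance(self):
        # increasing one pair's distance with all else fixed lowers affinity
        D = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 2.0], [4.0, 2.0, 0.0]])
        K, mu = 2, 0.8
        means = [(np.sort(D[i][D[i] > 0])[:K]).mean() for i in range(3)]
        vals = []
        for extra in (0.0, 1.0, 3.0):
            Dij = 4.0 + extra
            eps = (means[0] + means[2] + Dij) / 3.0
            vals.append(math.exp(-Dij / (mu * eps)))
        assert vals[0] > vals[1] > vals[2]


class TestFullKernel:
    def test_rows_sum_to_one(self, rng):
        W = random_affinity(rng, 7)
        P = full_kernel(W)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(np.diag(P), 0.5)

    def test_two_subjects(self):
        W = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert np.allclose(full_kernel(W), [[0.5, 0.5], [0.5, 0.5]])

    def test_matches_bruteforce(self, rng):
        W = random_affinity(rng, 5)
        P = full_kernel(W)
        for i in range(5):
            s = sum(W[i, j] for j in range(5) if j != i)
            for j in range(5):
                expect = 0.5 if i == j else W[i, j] / (2 * s)
                assert P[i, j] == pytest.approx(expect, abs=1e-14)

    def test_isolated_subject_rejected(self):
        W = np.eye(3)
        with pytest.raises(ValueError, match="isolated"):
            full_kernel(W, subject_ids=["a", "b", "c"])


class TestSparseKernel:
    def test_k_equals_n_minus_one_is_full_offdiagonal(self, rng):
        W = random_affinity(rng, 6)
        S = sparse_kernel(W, 5)
        off = W.copy()
        np.fill_diagonal(off, 0.0)
        assert np.allclose(S, off / off.sum(axis=1, keepdims=True), atol=1e-12)
        assert np.allclose(np.diag(S), 0.0)

    def test_k1_single_neighbour_per_row(self, rng):
        W = random_affinity(rng, 4)
        S = sparse_kernel(W, 1)
        assert np.all((S > 0).sum(axis=1) == 1)
        assert np.allclose(S.sum(axis=1), 1.0)

    def test_matches_bruteforce(self, rng):
        W = random_affinity(rng, 6)
        S = sparse_kernel(W, 3)
        for i in range(6):
            neigh = sorted((j for j in range(6) if j != i), key=lambda j: (-W[i, j], j))[:3]
            s = sum(W[i, j] for j in neigh)
            for j in range(6):
                expect = W[i, j] / s if j in neigh else 0.0
                assert S[i, j] == pytest.approx(expect, abs=1e-14)


def _affinities(rng, n, m, ids=None):
    ids = ids or [f"s{i}" for i in range(n)]
    return [AffinityMatrix(ids, random_affinity(rng, n)) for _ in range(m)]


class TestSnfFuse:
    def test_matches_naive_loop_implementation(self, rng):
        n = 20
        affs = _affinities(rng, n, 2)
        params = SNFParams(K=5, mu=0.8, T=5)
        fused = snf_fuse(affs, params)
        oracle = naive_snf([a.W for a in affs], K=5, T=5)
        assert np.max(np.abs(fused.S_fused - oracle)) < 1e-8

    def test_duplicate_modality_count_invariance(self, rng):
        n = 12
        W = random_affinity(rng, n)
        ids = [f"s{i}" for i in range(n)]
        p = SNFParams(K=4, T=10)
        f2 = snf_fuse([AffinityMatrix(ids, W)] * 2, p)
        f3 = snf_fuse([AffinityMatrix(ids, W)] * 3, p)
        assert np.max(np.abs(f2.S_fused - f3.S_fused)) < 1e-8

    def test_permutation_equivariance(self, rng):
        n = 10
        affs = _affinities(rng, n, 2)
        p = SNFParams(K=3, T=5)
        fused = snf_fuse(affs, p).S_fused
        perm = rng.permutation(n)
        permuted = [
            AffinityMatrix([a.subject_ids[i] for i in perm], a.W[np.ix_(perm, perm)])
            for a in affs
        ]
        fused_p = snf_fuse(permuted, p).S_fused
        assert np.allclose(fused_p, fused[np.ix_(perm, perm)], atol=1e-10)

    def test_block_structure_preserved(self, rng):
        # two modalities sharing a 3-block structure: fused within-block
        # similarity exceeds between-block similarity
        n_per, blocks = 8, 3
        n = n_per * blocks
        labels = np.repeat(np.arange(blocks), n_per)
        ids = [f"s{i}" for i in range(n)]
        affs = []
        for _ in range(2):
            centers = rng.normal(scale=4.0, size=(blocks, 5))
            X = centers[labels] + rng.normal(size=(n, 5))
            from fusemap.fusion import pairwise_sq_euclidean, scaled_exp_kernel

            W = scaled_exp_kernel(pairwise_sq_euclidean(X), SNFParams(K=5))
            affs.append(AffinityMatrix(ids, W))
        S = snf_fuse(affs, SNFParams(K=5, T=10)).S_fused
        off = ~np.eye(n, dtype=bool)
        same = (labels[:, None] == labels[None, :]) & off
        within = S[same].mean()
        between = S[(~(labels[:, None] == labels[None, :]))].mean()
        assert within > between

    def test_mismatched_ids_rejected(self, rng):
        a = _affinities(rng, 5, 1, ids=list("abcde"))[0]
        b = _affinities(rng, 5, 1, ids=list("abcdf"))[0]
        with pytest.raises(ValueError, match="mismatch"):
            snf_fuse([a, b], SNFParams(K=2))

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            SNFParams(K=2, T=0)

    @pytest.mark.parametrize("trial", range(20))
    def test_output_symmetric_nonnegative(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(6, 16))
        m = int(rng.integers(1, 4))
        affs = _affinities(rng, n, m)
        S = snf_fuse(affs, SNFParams(K=min(4, n - 1), T=5)).S_fused
        assert np.max(np.abs(S - S.T)) < 1e-10
        assert S.min() >= 0
        assert np.all(S.sum(axis=1) > 0)

    def test_small_cohort_k_clamped_with_warning(self, rng):
        affs = _affinities(rng, 6, 2)
        with pytest.warns(UserWarning, match="clamping"):
            snf_fuse(affs, SNFParams(K=30, T=3))
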