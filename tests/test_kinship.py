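"""Relationship matrices: tabular A, A^-1, GRM, weighted GRM, H^-1."""

from functools import lru_cache

import numpy as np
import pytest
import scipy.linalg as sla

from conftest import random_pedigree
from mbgp.kinship import (
    HInverse,
    SNPWeights,
    a_inverse,
    a_submatrix,
    blend_and_align_G,
    genomic_relationship,
    h_inverse,
    inbreeding_coefficients,
    numerator_relationship,
    weighted_genomic_relationship,
)


def polymorphic_panel(rng, n, m, p=0.45):
    """Binomial genotypes with every column polymorphic (redraw fixed ones)."""
    M = rng.binomial(2, p, size=(n, m))
    while True:
        freq = M.mean(axis=0) / 2
        bad = (freq == 0) | (freq == 1)
        if not bad.any():
            return M
        M[:, bad] = rng.binomial(2, p, size=(n, int(bad.sum())))


def recursive_kinship_matrix(sire, dam):
    """Independent oracle: memoized recursive coancestry; A = 2f."""

    @lru_cache(maxsize=None)
    def f(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return 0.5 * (1.0 + f(sire[i], dam[i]))
        if j > i:
            i, j = j, i
        return 0.5 * (f(sire[i], j) + f(dam[i], j))

    n = len(sire)
    sire = tuple(int(s) for s in sire)
    dam = tuple(int(d) for d in dam)
    return np.array([[2.0 * f(i, j) for j in range(n)] for i in range(n)])


class TestNumeratorRelationship:
    def test_unrelated_founders_identity(self):
        A = numerator_relationship([-1, -1, -1], [-1, -1, -1])
        assert np.array_equal(A, np.eye(3))

    def test_full_sibs_hand_values(self):
        # animals: 0 sire, 1 dam, 2 & 3 their full sibs
        sire = np.array([-1, -1, 0, 0])
        dam = np.array([-1, -1, 1, 1])
        A = numerator_relationship(sire, dam)
        assert A[2, 3] == pytest.approx(0.5)
        assert A[0, 2] == pytest.approx(0.5)
        assert np.allclose(np.diag(A), 1.0)

    def test_parent_offspring_mating_inbred_diagonal(self):
        # 2 = offspring of 0 x 1; 3 = offspring of 0 x 2 (parent-offspring)
        sire = np.array([-1, -1, 0, 0])
        dam = np.array([-1, -1, 1, 2])
        A = numerator_relationship(sire, dam)
        assert A[3, 3] == pytest.approx(1.25)
        assert inbreeding_coefficients(sire, dam)[3] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_recursive_kinship_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sire, dam = random_pedigree(rng, 50)
        A = numerator_relationship(sire, dam)
        assert np.allclose(A, recursive_kinship_matrix(sire, dam), atol=1e-12)

    def test_offspring_listed_before_parent_rejected(self):
        with pytest.raises(ValueError):
            numerator_relationship([1, -1], [-1, -1])


class TestAInverse:
    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_inverse_of_tabular_A(self, seed):
        rng = np.random.default_rng(seed)
        sire, dam = random_pedigree(rng, 40)
        A = numerator_relationship(sire, dam)
        F = inbreeding_coefficients(sire, dam)
        assert np.allclose(np.diag(A) - 1.0, F, atol=1e-12)
        A_inv = a_inverse(sire, dam, F).toarray()
        assert np.allclose(A_inv, np.linalg.inv(A), atol=1e-8)

    def test_submatrix_extraction(self, rng):
        sire, dam = random_pedigree(rng, 60)
        A = numerator_relationship(sire, dam)
        F = inbreeding_coefficients(sire, dam)
        idx = np.array([5, 17, 30, 59])
        A22 = a_submatrix(a_inverse(sire, dam, F), idx, chunk=3)
        assert np.allclose(A22, A[np.ix_(idx, idx)], atol=1e-8)


class TestGenomicRelationship:
    def test_hand_example_with_centering(self):
        M = np.array([[2, 2, 2], [0, 0, 0]])
        G = genomic_relationship(M, np.array([0.5, 0.5, 0.5]))
        assert np.allclose(G, [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicate_individuals_share_diagonal(self, rng):
        M = polymorphic_panel(rng, 5, 60)
        M[1] = M[0]
        freq = M.mean(axis=0) / 2
        M = M[:, (freq > 0) & (freq < 1)]
        G = genomic_relationship(M)
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_mean_diagonal_near_one_at_hwe(self, rng):
        p = rng.uniform(0.1, 0.9, size=3000)
        M = rng.binomial(2, p, size=(400, 3000))
        G = genomic_relationship(M, p)
        assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=0.03)

    def test_allele_label_flip_invariance(self, rng):
        M = rng.binomial(2, 0.3, size=(10, 30))
        p = M.mean(axis=0) / 2
        M2, p2 = M.copy(), p.copy()
        M2[:, 7] = 2 - M2[:, 7]
        p2[7] = 1 - p2[7]
        assert np.allclose(genomic_relationship(M, p), genomic_relationship(M2, p2))

    def test_monomorphic_column_rejected(self, rng):
        M = rng.binomial(2, 0.5, size=(10, 5))
        M[:, 2] = 0
        with pytest.raises(ValueError, match="monomorphic"):
            genomic_relationship(M)


class TestWeightedGenomicRelationship:
    def test_identity_weights_recover_plain_G(self, rng):
        M = rng.binomial(2, 0.4, size=(12, 40))
        p = M.mean(axis=0) / 2
        Gw = weighted_genomic_relationship(M, p, np.ones(40))
        assert np.allclose(Gw, genomic_relationship(M, p))

    def test_single_nonzero_weight_matches_direct_computation(self, rng):
        M = rng.binomial(2, 0.4, size=(3, 6)).astype(float)
        p = np.full(6, 0.45)
        w = np.zeros(6)
        w[2] = 2.0
        Gw = weighted_genomic_relationship(M, p, w)
        z = M[:, 2] - 2 * p[2]
        expected = 2.0 * np.outer(z, z) / (np.sum(2 * p * (1 - p)) * np.mean(w))
        assert np.allclose(Gw, expected)

    def test_positive_semidefinite_for_any_weights(self, rng):
        M = rng.binomial(2, 0.5, size=(15, 50))
        w = rng.uniform(0, 3, size=50)
        Gw = weighted_genomic_relationship(M, None, w)
        assert np.min(np.linalg.eigvalsh(Gw)) > -1e-10

    def test_negative_weight_rejected(self, rng):
        M = rng.binomial(2, 0.5, size=(5, 4))
        with pytest.raises(ValueError):
            weighted_genomic_relationship(M, None, np.array([1.0, -0.1, 1.0, 1.0]))


class TestBlendAndAlign:
    def test_aligned_full_blend_is_identity_operation(self, rng):
        A22 = np.eye(4) + 0.1
        G = A22.copy()
        assert np.allclose(blend_and_align_G(G, A22, 1.0), G)

    def test_mean_diagonal_matches_A22(self, rng):
        M = rng.binomial(2, 0.4, size=(8, 100))
        G = genomic_relationship(M)
        A22 = np.eye(8) * 1.02
        G_star = blend_and_align_G(G, A22, 0.95)
        assert np.mean(np.diag(G_star)) == pytest.approx(np.mean(np.diag(A22)), abs=1e-10)

    def test_repairs_singular_G(self, rng):
        M = rng.binomial(2, 0.4, size=(6, 80))
        M[1] = M[0]  # duplicate animal -> singular G
        G = genomic_relationship(M)
        G_star = blend_and_align_G(G, np.eye(6), 0.95)
        sla.solve(G_star, np.ones(6))  # must not raise; PD after blending
        assert np.linalg.matrix_rank(G_star) == 6

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            blend_and_align_G(np.eye(3), np.eye(4))


def dense_h_oracle(A, G_star, idx):
    """Build H directly from its closed form and invert it densely."""
    n = len(A)
    others = np.setdiff1d(np.arange(n), idx)
    order = np.concatenate([others, idx])
    Ao = A[np.ix_(order, order)]
    n1 = len(others)
    A11, A12, A22 = Ao[:n1, :n1], Ao[:n1, n1:], Ao[n1:, n1:]
    A22_inv = np.linalg.inv(A22)
    H11 = A11 + A12 @ A22_inv @ (G_star - A22) @ A22_inv @ A12.T
    H12 = A12 @ A22_inv @ G_star
    H = np.block([[H11, H12], [H12.T, G_star]])
    H_inv_o = np.linalg.inv(H)
    inv_order = np.argsort(order)
    return H_inv_o[np.ix_(inv_order, inv_order)]


class TestHInverse:
    def _pedigree(self, rng, n=8):
        sire, dam = random_pedigree(rng, n)
        A = numerator_relationship(sire, dam)
        F = inbreeding_coefficients(sire, dam)
        return sire, dam, A, F

    def test_G_star_equal_A22_collapses_to_A_inverse(self, rng):
        sire, dam, A, F = self._pedigree(rng)
        idx = np.array([4, 6, 7])
        A22 = A[np.ix_(idx, idx)]
        A_inv = a_inverse(sire, dam, F)
        H_inv = h_inverse(A_inv, np.linalg.inv(A22), np.linalg.inv(A22), idx)
        assert np.allclose(H_inv.to_dense(), A_inv.toarray(), atol=1e-10)

    def test_no_genotyped_animals(self, rng):
        sire, dam, A, F = self._pedigree(rng)
        A_inv = a_inverse(sire, dam, F)
        H_inv = h_inverse(A_inv, np.empty((0, 0)), np.empty((0, 0)), np.array([], int))
        assert np.allclose(H_inv.to_dense(), A_inv.toarray())

    @pytest.mark.parametrize("seed", [11, 12])
    def test_matches_dense_H_inversion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sire, dam, A, F = self._pedigree(rng, n=10)
        idx = np.array([3, 7, 8, 9])
        M = polymorphic_panel(rng, 4, 60)
        G = genomic_relationship(M)
        A22 = A[np.ix_(idx, idx)]
        G_star = blend_and_align_G(G, A22, 0.95)
        H_inv = h_inverse(
            a_inverse(sire, dam, F), np.linalg.inv(A22), np.linalg.inv(G_star), idx
        )
        assert np.allclose(H_inv.to_dense(), dense_h_oracle(A, G_star, idx), atol=1e-8)

    def test_matvec_consistent_with_dense_and_symmetric(self, rng):
        sire, dam, A, F = self._pedigree(rng, n=12)
        idx = np.array([9, 10, 11])
        corr = rng.normal(size=(3, 3))
        corr = corr + corr.T
        H_inv = HInverse(a_inverse(sire, dam, F), corr, idx)
        x = rng.normal(size=12)
        dense = H_inv.to_dense()
        assert np.allclose(H_inv @ x, dense @ x)
        assert np.allclose(dense, dense.T)
        assert np.allclose(H_inv.diagonal(), np.diag(dense))

    def test_index_out_of_range_rejected(self, rng):
        sire, dam, A, F = self._pedigree(rng)
        with pytest.raises(ValueError):
            h_inverse(a_inverse(sire, dam, F), np.eye(1), np.eye(1), np.array([99]))


def test_snp_weights_validate_nonnegativity():
    with pytest.raises(ValueError):
        SNPWeights(w=np.array([1.0, -0.5]), window_halfwidth=1, scaling_constant=1.0)
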