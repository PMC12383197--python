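"""Mixed-model solvers: PBLUP, GBLUP, ssGBLUP, wGBLUP, accuracy."""

import numpy as np
import pytest
import scipy.sparse as sp

from conftest import random_pedigree
from mbgp.kinship import (
    a_inverse,
    blend_and_align_G,
    genomic_relationship,
    inbreeding_coefficients,
    numerator_relationship,
)
from mbgp.models import (
    EvaluationResult,
    MixedModelSpec,
    accuracy,
    estimate_snp_effects,
    lambda_from_h2,
    run_gblup,
    run_pblup,
    run_ssgblup,
    run_wgblup,
    solve_gls,
    solve_mme,
    window_weights,
)
from test_kinship import polymorphic_panel


def dense_mme_oracle(y, X, Z, K_inv, lam):
    """Direct dense solve of Henderson's equations."""
    X = np.atleast_2d(X)
    Z = Z.toarray() if sp.issparse(Z) else np.asarray(Z)
    top = np.hstack([X.T @ X, X.T @ Z])
    bottom = np.hstack([Z.T @ X, Z.T @ Z + lam * K_inv])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[: X.shape[1]], sol[X.shape[1] :]


def _incidence(rows, q):
    return sp.csr_matrix((np.ones(len(rows)), (np.arange(len(rows)), rows)), shape=(len(rows), q))


class TestSolveMme:
    def test_identity_K_equals_ridge_oracle(self, rng):
        y = rng.normal(size=5)
        X = np.ones((5, 1))
        Z = _incidence(np.arange(5), 5)
        spec = MixedModelSpec(y=y, X=X, Z=Z, K_inv=np.eye(5), lam=1.381)
        res = solve_mme(spec, tolerance=1e-12)
        b, g = dense_mme_oracle(y, X, Z, np.eye(5), 1.381)
        assert res.converged
        assert np.allclose(res.fixed_effects, b, atol=1e-8)
        assert np.allclose(res.gebv, g, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_pd_K_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q, r = 12, 8
        L = rng.normal(size=(q, q))
        K = L @ L.T + q * np.eye(q)
        K_inv = np.linalg.inv(K)
        rows = rng.integers(0, q, size=r)
        y = rng.normal(size=r)
        X = np.column_stack([np.ones(r), rng.normal(size=r)])
        Z = _incidence(rows, q)
        spec = MixedModelSpec(y=y, X=X, Z=Z, K_inv=K_inv, lam=0.7)
        res = solve_mme(spec, tolerance=1e-12)
        b, g = dense_mme_oracle(y, X, Z, K_inv, 0.7)
        assert np.allclose(res.fixed_effects, b, atol=1e-6)
        assert np.allclose(res.gebv, g, atol=1e-6)

    def test_infinite_shrinkage_limit(self, rng):
        y = rng.normal(size=20)
        spec = MixedModelSpec(
            y=y, X=np.ones((20, 1)), Z=_incidence(np.arange(20), 20), K_inv=np.eye(20), lam=1e8
        )
        res = solve_mme(spec)
        assert np.allclose(res.gebv, 0.0, atol=1e-5)
        assert res.fixed_effects[0] == pytest.approx(y.mean(), abs=1e-5)

    def test_gls_equivalent_to_mme_on_pd_K(self, rng):
        q, r = 10, 7
        M = polymorphic_panel(rng, q, 40)
        K = genomic_relationship(M) + 0.05 * np.eye(q)
        rows = rng.choice(q, size=r, replace=False)
        y = rng.normal(size=r)
        res_gls = solve_gls(y, np.ones((r, 1)), _incidence(rows, q), K, 1.381)
        spec = MixedModelSpec(
            y=y, X=np.ones((r, 1)), Z=_incidence(rows, q), K_inv=np.linalg.inv(K), lam=1.381
        )
        res_mme = solve_mme(spec, tolerance=1e-12)
        assert np.allclose(res_gls.gebv, res_mme.gebv, atol=1e-7)
        assert np.allclose(res_gls.fixed_effects, res_mme.fixed_effects, atol=1e-7)

    def test_nonconvergence_flagged(self, rng):
        y = rng.normal(size=30)
        spec = MixedModelSpec(
            y=y, X=np.ones((30, 1)), Z=_incidence(np.arange(30), 30), K_inv=np.eye(30), lam=1.0
        )
        res = solve_mme(spec, tolerance=1e-14, max_iter=1)
        assert not res.converged


class TestPblup:
    def test_founders_only_reduces_to_ridge(self, rng):
        y = rng.normal(size=6)
        res = run_pblup(np.full(6, -1), np.full(6, -1), np.arange(6), y, lam=2.0)
        b, g = dense_mme_oracle(y, np.ones((6, 1)), _incidence(np.arange(6), 6), np.eye(6), 2.0)
        assert np.allclose(res.gebv, g, atol=1e-7)

    def test_sire_with_progeny_matches_dense_oracle(self, rng):
        # animal 0: sire of 8 phenotyped half-sibs (dams unknown); no record itself
        n_prog = 8
        sire = np.array([-1] + [0] * n_prog)
        dam = np.full(1 + n_prog, -1)
        y = rng.normal(0.5, 1.0, size=n_prog)
        rows = np.arange(1, n_prog + 1)
        res = run_pblup(sire, dam, rows, y, lam=1.381)
        A = numerator_relationship(sire, dam)
        b, g = dense_mme_oracle(
            y, np.ones((n_prog, 1)), _incidence(rows, 1 + n_prog), np.linalg.inv(A), 1.381
        )
        assert np.allclose(res.gebv, g, atol=1e-6)
        assert res.gebv[0] != 0.0  # parent EBV driven by progeny records

    def test_unphenotyped_relatives_receive_ebvs(self, rng):
        sire, dam = random_pedigree(rng, 30)
        rows = np.arange(10, 25)
        y = rng.normal(size=15)
        res = run_pblup(sire, dam, rows, y)
        assert len(res.gebv) == 30 and np.all(np.isfinite(res.gebv))


class TestGblup:
    def test_duplicate_candidate_gets_equal_gebv(self, rng):
        M_ref = polymorphic_panel(rng, 15, 80)
        M_cand = M_ref[[3]].copy()  # candidate is a genotypic duplicate of ref 3
        y = rng.normal(size=15)
        M = np.vstack([M_ref, M_cand])
        freq = M.mean(axis=0) / 2
        keep = (freq > 0) & (freq < 1)
        K = genomic_relationship(M[:, keep])  # singular: duplicate rows
        res = run_gblup(M_ref, M_cand, y, lam=1.381, K=K)
        assert res.gebv[15] == pytest.approx(res.gebv[3], abs=1e-10)

    def test_matches_dense_gls_oracle(self, rng):
        M_ref = polymorphic_panel(rng, 20, 50)
        M_cand = polymorphic_panel(rng, 5, 50)
        y = rng.normal(size=20)
        res = run_gblup(M_ref, M_cand, y, lam=1.381, ridge=0.01)
        K = res.extras["K"]
        # independent oracle: GLS formulas evaluated with plain inverses
        Z = np.zeros((20, 25))
        Z[np.arange(20), np.arange(20)] = 1.0
        V = Z @ K @ Z.T + 1.381 * np.eye(20)
        Vi = np.linalg.inv(V)
        X = np.ones((20, 1))
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        g = K @ Z.T @ Vi @ (y - X @ b)
        assert np.allclose(res.gebv, g, atol=1e-6)

    def test_missing_reference_records_are_ignored(self, rng):
        M_ref = polymorphic_panel(rng, 12, 40)
        y = rng.normal(size=12)
        y[[2, 5]] = np.nan
        res = run_gblup(M_ref, M_ref[:2], y, lam=1.381)
        assert np.all(np.isfinite(res.gebv))

    def test_default_lambda_from_heritability(self):
        assert lambda_from_h2(0.42) == pytest.approx(0.58 / 0.42)


class TestSnpBlupEquivalence:
    def test_snp_blup_equals_gblup_with_identity_weights(self, rng):
        """SNP-BLUP and GRM GBLUP are the same model at matched variances."""
        n_ref, n_cand, m = 20, 6, 60
        M = polymorphic_panel(rng, n_ref + n_cand, m)
        p = M.mean(axis=0) / 2
        y = rng.normal(size=n_ref)
        alpha = estimate_snp_effects(M[:n_ref], y, allele_freqs=p, h2=0.42)
        gebv_snp = (M - 2 * p) @ alpha
        G = genomic_relationship(M, p)
        res = run_gblup(M[:n_ref], M[n_ref:], y, lam=lambda_from_h2(0.42), K=G)
        assert np.allclose(gebv_snp, res.gebv, atol=1e-6)

    def test_dense_ridge_oracle(self, rng):
        n, m = 12, 10
        M = polymorphic_panel(rng, n, m)
        p = M.mean(axis=0) / 2
        Zc = M - 2 * p
        y = rng.normal(size=n)
        lam_snp = 3.7
        alpha = estimate_snp_effects(M, y, lambda_snp=lam_snp, allele_freqs=p)
        # oracle: joint dense solve of [mu; alpha] normal equations
        Xa = np.hstack([np.ones((n, 1)), Zc])
        lhs = Xa.T @ Xa + lam_snp * np.diag([0.0] + [1.0] * m)
        lhs[0, 0] = n  # no penalty on the intercept
        sol = np.linalg.solve(lhs, Xa.T @ y)
        assert np.allclose(alpha, sol[1:], atol=1e-8)

    def test_single_causal_marker_dominates(self, rng):
        n, m = 80, 30
        M = polymorphic_panel(rng, n, m)
        y = 2.0 * (M[:, 11] - M[:, 11].mean())
        alpha = estimate_snp_effects(M, y)
        assert np.argmax(np.abs(alpha)) == 11


class TestWindowWeights:
    def test_hand_oracle(self):
        w = window_weights(np.array([1.0, 0.0, 0.0, 0.0, 2.0]), S=1)
        raw = np.array([0.5, 1 / 3, 0.0, 4 / 3, 2.0])
        expected = raw / raw.mean()
        assert np.allclose(w.w, expected)
        assert w.w.mean() == pytest.approx(1.0)

    def test_flat_effects_give_unit_weights(self):
        w = window_weights(np.full(10, 0.3), S=3)
        assert np.allclose(w.w, 1.0)

    def test_point_window_is_squared_effect(self, rng):
        a = rng.normal(size=20)
        w = window_weights(a, S=0)
        assert np.allclose(w.w, a**2 / np.mean(a**2))

    def test_empty_effects_rejected(self):
        with pytest.raises(ValueError):
            window_weights(np.array([]), S=1)

    def test_all_zero_effects_fall_back_to_flat(self):
        w = window_weights(np.zeros(7), S=2)
        assert np.allclose(w.w, 1.0)


class TestWgblup:
    def test_flat_weights_collapse_to_gblup(self, rng):
        # equal pass-1 effects => unit window weights => weighted GRM == GRM
        from mbgp.kinship import weighted_genomic_relationship

        M = polymorphic_panel(rng, 10, 30)
        p = M.mean(axis=0) / 2
        w = window_weights(np.full(30, 0.2), S=5)
        assert np.allclose(
            weighted_genomic_relationship(M, p, w), genomic_relationship(M, p), atol=1e-12
        )

    def test_weights_used_in_pass_two_have_unit_mean(self, rng):
        M_ref = polymorphic_panel(rng, 30, 50)
        y = rng.normal(size=30)
        res = run_wgblup(M_ref, M_ref[:3], y, S=5)
        assert res.extras["snp_weights"].w.mean() == pytest.approx(1.0)

    def test_upweights_region_of_large_effect(self, rng):
        n, m = 150, 60
        M = polymorphic_panel(rng, n, m)
        tbv = 1.5 * (M[:, 30] - M[:, 30].mean())
        y = tbv + rng.normal(0, 0.5, size=n)
        res = run_wgblup(M, M[:5], y, S=2)
        w = res.extras["snp_weights"].w
        assert w[30] > 1.0


class TestSsgblup:
    def test_empty_genotyped_set_equals_pblup(self, rng):
        sire, dam = random_pedigree(rng, 25)
        rows = np.arange(10, 20)
        y = rng.normal(size=10)
        res_ss = run_ssgblup(sire, dam, rows, y, np.array([], int), None, lam=1.381)
        res_pb = run_pblup(sire, dam, rows, y, lam=1.381)
        assert np.allclose(res_ss.gebv, res_pb.gebv, atol=1e-8)

    def test_G_star_equal_A22_equals_pblup(self, rng):
        sire, dam = random_pedigree(rng, 25)
        A = numerator_relationship(sire, dam)
        idx = np.array([20, 21, 22, 23, 24])
        A22 = A[np.ix_(idx, idx)]
        rows = np.arange(5, 20)
        y = rng.normal(size=15)
        # G = A22 -> alignment and blending leave G* = A22 -> H^-1 = A^-1
        res_ss = run_ssgblup(sire, dam, rows, y, idx, None, lam=1.381, A22=A22, G=A22.copy())
        res_pb = run_pblup(sire, dam, rows, y, lam=1.381)
        assert np.allclose(res_ss.gebv, res_pb.gebv, atol=1e-7)

    def test_toy_matches_dense_H_oracle(self, rng):
        from test_kinship import dense_h_oracle

        sire, dam = random_pedigree(rng, 6, founder_fraction=0.5)
        A = numerator_relationship(sire, dam)
        F = inbreeding_coefficients(sire, dam)
        idx = np.array([3, 4, 5])
        M = polymorphic_panel(rng, 3, 40)
        G = genomic_relationship(M)
        A22 = A[np.ix_(idx, idx)]
        G_star = blend_and_align_G(G, A22, 0.95)
        rows = np.arange(6)
        y = rng.normal(size=6)
        res = run_ssgblup(sire, dam, rows, y, idx, M, lam=1.381, F=F, A22=A22, blend_weight=0.95)
        H_inv = dense_h_oracle(A, G_star, idx)
        b, g = dense_mme_oracle(y, np.ones((6, 1)), _incidence(rows, 6), H_inv, 1.381)
        assert np.allclose(res.gebv, g, atol=1e-6)

    def test_all_genotyped_equals_gblup_on_same_records(self, rng):
        n = 10
        p_true = rng.uniform(0.25, 0.75, size=120)
        M = rng.binomial(2, p_true, size=(n, 120))
        # external (true) frequencies keep G full rank; observed frequencies
        # would center the rows to sum zero and make G singular by construction
        G = genomic_relationship(M, p_true)
        G = G / np.mean(np.diag(G))  # align mean diagonal with A22 = I exactly
        sire = np.full(n, -1)
        dam = np.full(n, -1)
        rows = np.arange(6)
        y = rng.normal(size=6)
        res_ss = run_ssgblup(
            sire, dam, rows, y, np.arange(n), M, lam=1.381, A22=np.eye(n), G=G, blend_weight=1.0
        )
        res_g = run_gblup(M[:6], M[6:], y, lam=1.381, K=G)
        assert np.allclose(res_ss.gebv, res_g.gebv, atol=1e-6)


class TestAccuracy:
    def test_perfect_and_inverted(self, rng):
        t = rng.normal(size=10)
        assert accuracy(t, t) == pytest.approx(1.0)
        assert accuracy(-t, t) == pytest.approx(-1.0)

    def test_hand_example_closed_form(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        t = np.array([2.0, 4.0, 5.0, 9.0])
        n = 4
        num = n * np.sum(g * t) - g.sum() * t.sum()
        den = np.sqrt(n * np.sum(g**2) - g.sum() ** 2) * np.sqrt(n * np.sum(t**2) - t.sum() ** 2)
        assert accuracy(g, t) == pytest.approx(num / den)

    def test_affine_invariance_with_positive_slope(self, rng):
        g, t = rng.normal(size=20), rng.normal(size=20)
        assert accuracy(3.0 * g + 1.0, t) == pytest.approx(accuracy(g, t))

    def test_subset_selection(self, rng):
        g, t = rng.normal(size=30), rng.normal(size=30)
        sub = np.arange(10, 30)
        assert accuracy(g, t, sub) == pytest.approx(np.corrcoef(g[sub], t[sub])[0, 1])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            accuracy(np.arange(5.0), np.arange(5.0), np.array([], int))
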