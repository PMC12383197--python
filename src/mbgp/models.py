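"""Breeding-value prediction models: PBLUP, GBLUP, ssGBLUP, wGBLUP.

All models are single-trait animal models with an intercept as the only
fixed effect and a known variance ratio lambda = sigma_e^2 / sigma_g^2
(0.58/0.42 under the default heritability of 0.42). Henderson's mixed
model equations

    [X'X   X'Z        ] [b]   [X'y]
    [Z'X   Z'Z + l K^-1] [g] = [Z'y]

are solved by Jacobi-preconditioned conjugate gradients; models whose
relationship matrix K is available (rather than its inverse) may instead
use the mathematically equivalent GLS form in record space,
b = (X'V^-1X)^-1 X'V^-1 y, g = K Z' V^-1 (y - Xb), V = Z K Z' + l I,
which stays defined when K is singular (e.g. duplicated genotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, cg

from . import kinship
from .kinship import SNPWeights

__all__ = [
    "MixedModelSpec",
    "EvaluationResult",
    "solve_mme",
    "solve_gls",
    "run_pblup",
    "run_gblup",
    "run_ssgblup",
    "estimate_snp_effects",
    "window_weights",
    "run_wgblup",
    "accuracy",
]

DEFAULT_H2 = 0.42


def lambda_from_h2(h2: float) -> float:
    if not 0.0 < h2 < 1.0:
        raise ValueError("heritability must be in (0, 1)")
    return (1.0 - h2) / h2


@dataclass
class MixedModelSpec:
    """One mixed-model system: phenotypes, incidences and the K structure.

    ``K_inv`` may be a dense array, a sparse matrix, or a LinearOperator
    exposing ``diagonal()`` (the single-step H^-1 is kept in factored form).
    """

    y: np.ndarray
    X: np.ndarray
    Z: sp.spmatrix
    K_inv: object
    lam: float

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != len(self.y):
            self.X = self.X.T
        self.Z = sp.csr_matrix(self.Z)
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.Z.shape[0] != len(self.y) or self.X.shape[0] != len(self.y):
            raise ValueError("rows of y, X, Z disagree")
        if np.any(np.asarray(self.Z.sum(axis=1)).ravel() != 1):
            raise ValueError("every record must map to exactly one animal")


@dataclass
class EvaluationResult:
    gebv: np.ndarray
    fixed_effects: np.ndarray
    converged: bool = True
    iterations: int = 0
    animal_ids: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def _kinv_diagonal(K_inv) -> np.ndarray:
    if sp.issparse(K_inv):
        return np.asarray(K_inv.diagonal(), dtype=float)
    if isinstance(K_inv, np.ndarray):
        return np.diag(K_inv).astype(float)
    return np.asarray(K_inv.diagonal(), dtype=float)  # HInverse / operator


def _kinv_matvec(K_inv, x: np.ndarray) -> np.ndarray:
    return np.asarray(K_inv @ x, dtype=float).ravel()


def solve_mme(spec: MixedModelSpec, tolerance: float = 1e-8, max_iter: int = 10_000) -> EvaluationResult:
    """Solve Henderson's equations by preconditioned conjugate gradients."""
    X, Z, y, lam, K_inv = spec.X, spec.Z, spec.y, spec.lam, spec.K_inv
    p = X.shape[1]
    q = Z.shape[1]

    XtX = X.T @ X
    ZtZ_diag = np.asarray(Z.multiply(Z).sum(axis=0)).ravel()

    def matvec(v):
        b, g = v[:p], v[p:]
        Zg = Z @ g
        top = X.T @ (X @ b) + X.T @ Zg
        bottom = Z.T @ (X @ b) + Z.T @ Zg + lam * _kinv_matvec(K_inv, g)
        return np.concatenate([top, bottom])

    rhs = np.concatenate([X.T @ y, Z.T @ y])
    op = LinearOperator((p + q, p + q), matvec=matvec, dtype=float)

    diag = np.concatenate([np.diag(XtX), ZtZ_diag + lam * _kinv_diagonal(K_inv)])
    diag = np.where(diag > 0, diag, 1.0)
    precond = LinearOperator((p + q, p + q), matvec=lambda v: v / diag, dtype=float)

    iters = 0

    def count(_):
        nonlocal iters
        iters += 1

    sol, info = cg(op, rhs, rtol=tolerance, atol=0.0, maxiter=max_iter, M=precond, callback=count)
    converged = info == 0
    return EvaluationResult(
        gebv=sol[p:], fixed_effects=sol[:p], converged=converged, iterations=iters
    )


def solve_gls(
    y: np.ndarray, X: np.ndarray, Z: sp.spmatrix, K: np.ndarray, lam: float
) -> EvaluationResult:
    """Equivalent GLS solution in record space (valid for singular K)."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    Z = sp.csr_matrix(Z)
    ZK = Z @ K
    V = ZK @ Z.T.toarray() if sp.issparse(Z) else ZK @ Z.T
    V = np.asarray(V) + lam * np.eye(len(y))
    cho = sla.cho_factor(V, lower=True)
    Vinv_X = sla.cho_solve(cho, X)
    Vinv_y = sla.cho_solve(cho, y)
    b = np.linalg.solve(X.T @ Vinv_X, X.T @ Vinv_y)
    resid_weights = Vinv_y - Vinv_X @ b
    g = ZK.T @ resid_weights if not sp.issparse(ZK) else np.asarray(ZK.T @ resid_weights)
    return EvaluationResult(gebv=np.asarray(g).ravel(), fixed_effects=np.atleast_1d(b))


def _incidence(record_animal_idx: np.ndarray, n_animals: int) -> sp.csr_matrix:
    r = len(record_animal_idx)
    return sp.csr_matrix(
        (np.ones(r), (np.arange(r), np.asarray(record_animal_idx, dtype=np.int64))),
        shape=(r, n_animals),
    )


def run_pblup(
    sire: np.ndarray,
    dam: np.ndarray,
    record_animal_idx: np.ndarray,
    y: np.ndarray,
    lam: float = lambda_from_h2(DEFAULT_H2),
    F: np.ndarray | None = None,
    tolerance: float = 1e-8,
    max_iter: int = 10_000,
) -> EvaluationResult:
    """Pedigree BLUP: Henderson's sparse A^-1 in the mixed-model equations.

    Returns EBVs for every animal in the pedigree, phenotyped or not.
    """
    n = len(sire)
    if F is None:
        F = kinship.inbreeding_coefficients(sire, dam)
    A_inv = kinship.a_inverse(sire, dam, F)
    y = np.asarray(y, dtype=float)
    X = np.ones((len(y), 1))
    spec = MixedModelSpec(y=y, X=X, Z=_incidence(record_animal_idx, n), K_inv=A_inv, lam=lam)
    return solve_mme(spec, tolerance=tolerance, max_iter=max_iter)


def condition_grm(G: np.ndarray, ridge: float = 0.01) -> np.ndarray:
    """Shrink G slightly toward a scaled identity so it is invertible."""
    G = np.asarray(G, dtype=float)
    return (1.0 - ridge) * G + ridge * np.mean(np.diag(G)) * np.eye(len(G))


def run_gblup(
    reference_genotypes: np.ndarray,
    candidate_genotypes: np.ndarray,
    y_reference: np.ndarray,
    lam: float = lambda_from_h2(DEFAULT_H2),
    K: np.ndarray | None = None,
    ridge: float = 0.01,
) -> EvaluationResult:
    """GBLUP over reference + candidates; candidates carry no records.

    The GRM is built on the joint set with observed allele frequencies;
    monomorphic markers in the joint set are excluded. Solved in record
    space (GLS), which is exact and robust to duplicated genotypes.
    """
    M_ref = np.asarray(reference_genotypes, dtype=float)
    M_cand = np.asarray(candidate_genotypes, dtype=float)
    M = np.vstack([M_ref, M_cand]) if len(M_cand) else M_ref
    if K is None:
        p = M.mean(axis=0) / 2.0
        keep = (p > 0.0) & (p < 1.0)
        if not keep.all():
            import warnings

            warnings.warn(f"excluding {int((~keep).sum())} monomorphic markers from the GRM")
        G = kinship.genomic_relationship(M[:, keep], p[keep])
        K = condition_grm(G, ridge) if ridge > 0 else G
    n_ref = len(M_ref)
    y = np.asarray(y_reference, dtype=float)
    if len(y) != n_ref:
        raise ValueError("reference phenotype length mismatch")
    rec = np.flatnonzero(~np.isnan(y))  # reference animals without a record stay in G only
    if rec.size == 0:
        raise ValueError("no phenotype records in the reference")
    Z = _incidence(rec, len(M))
    X = np.ones((len(rec), 1))
    res = solve_gls(y[rec], X, Z, K, lam)
    res.extras["K"] = K
    return res


def run_ssgblup(
    sire: np.ndarray,
    dam: np.ndarray,
    record_animal_idx: np.ndarray,
    y: np.ndarray,
    genotyped_index: np.ndarray,
    genotypes: np.ndarray,
    lam: float = lambda_from_h2(DEFAULT_H2),
    blend_weight: float = 0.95,
    F: np.ndarray | None = None,
    A22: np.ndarray | None = None,
    tolerance: float = 1e-8,
    max_iter: int = 10_000,
    G: np.ndarray | None = None,
) -> EvaluationResult:
    """Single-step GBLUP: H^-1 combines the full pedigree with the GRM.

    ``genotyped_index`` locates genotyped animals inside the pedigree
    ordering. With an empty genotyped set this reduces exactly to PBLUP.
    """
    n = len(sire)
    genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
    if F is None:
        F = kinship.inbreeding_coefficients(sire, dam)
    A_inv = kinship.a_inverse(sire, dam, F)

    if len(genotyped_index) == 0:
        K_inv = A_inv
    else:
        if G is None:
            M = np.asarray(genotypes, dtype=float)
            p = M.mean(axis=0) / 2.0
            keep = (p > 0.0) & (p < 1.0)
            G = kinship.genomic_relationship(M[:, keep], p[keep])
        if A22 is None:
            A22 = kinship.a_submatrix(A_inv, genotyped_index)
        G_star = kinship.blend_and_align_G(G, A22, blend_weight)
        G_star_inv = sla.inv(G_star)
        A22_inv = sla.inv(A22)
        K_inv = kinship.h_inverse(A_inv, A22_inv, G_star_inv, genotyped_index)

    y = np.asarray(y, dtype=float)
    X = np.ones((len(y), 1))
    spec = MixedModelSpec(y=y, X=X, Z=_incidence(record_animal_idx, n), K_inv=K_inv, lam=lam)
    return solve_mme(spec, tolerance=tolerance, max_iter=max_iter)


def estimate_snp_effects(
    reference_genotypes: np.ndarray,
    phenotypes: np.ndarray,
    weights: np.ndarray | None = None,
    lambda_snp: float | None = None,
    allele_freqs: np.ndarray | None = None,
    h2: float = DEFAULT_H2,
) -> np.ndarray:
    """Ridge (SNP-BLUP) estimates of per-marker effects.

    The model is y = 1 mu + Zc alpha + e with Zc the centered genotypes and
    alpha_j ~ N(0, w_j sigma_alpha^2). With w = 1 and
    sigma_alpha^2 = sigma_g^2 / sum 2 p (1-p), predictions Zc alpha-hat
    equal GBLUP's GEBVs exactly. Solved in the (small) record space.
    """
    M = np.asarray(reference_genotypes, dtype=float)
    n, m = M.shape
    p = M.mean(axis=0) / 2.0 if allele_freqs is None else np.asarray(allele_freqs, dtype=float)
    if np.any(M.var(axis=0) == 0.0) and allele_freqs is None:
        raise ValueError("zero-variance marker column in reference genotypes")
    w = np.ones(m) if weights is None else np.asarray(
        weights.w if isinstance(weights, SNPWeights) else weights, dtype=float
    )
    if np.any(w < 0):
        raise ValueError("SNP weights must be non-negative")
    if lambda_snp is None:
        # lambda_snp = sigma_e^2 / sigma_alpha^2 with the GBLUP-equivalent scaling
        lam = lambda_from_h2(h2)
        lambda_snp = lam * float(np.sum(2.0 * p * (1.0 - p)))
    Zc = M - 2.0 * p
    y = np.asarray(phenotypes, dtype=float).ravel()
    V = (Zc * w) @ Zc.T + lambda_snp * np.eye(n)
    cho = sla.cho_factor(V, lower=True)
    ones = np.ones(n)
    Vinv_1 = sla.cho_solve(cho, ones)
    Vinv_y = sla.cho_solve(cho, y)
    mu = float(ones @ Vinv_y) / float(ones @ Vinv_1)
    alpha = (Zc * w).T @ (Vinv_y - Vinv_1 * mu)
    return alpha


def window_weights(alpha_hat: np.ndarray, S: int) -> SNPWeights:
    """Windowed squared-effect SNP weights.

    w_j is proportional to the mean of alpha-hat^2 over markers j-S..j+S
    (window clipped at the array bounds); the constant C rescales the
    weights to mean 1.
    """
    a2 = np.asarray(alpha_hat, dtype=float) ** 2
    if a2.size == 0:
        raise ValueError("empty SNP-effect vector")
    if S < 0:
        raise ValueError("window half-width must be >= 0")
    S_eff = min(S, len(a2) - 1)  # convolve('same') misbehaves if kernel > array
    kernel = np.ones(2 * S_eff + 1)
    sums = np.convolve(a2, kernel, mode="same")
    counts = np.convolve(np.ones_like(a2), kernel, mode="same")
    raw = sums / counts
    mean_raw = raw.mean()
    if mean_raw == 0.0:
        # all effects zero: fall back to flat weights
        return SNPWeights(w=np.ones_like(raw), window_halfwidth=S, scaling_constant=1.0)
    C = 1.0 / mean_raw
    return SNPWeights(w=C * raw, window_halfwidth=S, scaling_constant=C)


def run_wgblup(
    reference_genotypes: np.ndarray,
    candidate_genotypes: np.ndarray,
    y_reference: np.ndarray,
    S: int = 20,
    lam: float = lambda_from_h2(DEFAULT_H2),
    h2: float = DEFAULT_H2,
    ridge: float = 0.01,
) -> EvaluationResult:
    """Two-pass window-weighted GBLUP.

    Pass 1 estimates SNP effects on the training records with identity
    weights; pass 2 rebuilds the GRM with windowed squared-effect weights
    and refits. Candidates never contribute to the weights.
    """
    M_ref = np.asarray(reference_genotypes, dtype=float)
    M_cand = np.asarray(candidate_genotypes, dtype=float)
    M = np.vstack([M_ref, M_cand]) if len(M_cand) else M_ref
    p = M.mean(axis=0) / 2.0
    keep = (p > 0.0) & (p < 1.0)
    M_ref, M_cand, M, p = M_ref[:, keep], M_cand[:, keep], M[:, keep], p[keep]

    y_ref = np.asarray(y_reference, dtype=float)
    rec = np.flatnonzero(~np.isnan(y_ref))
    alpha = estimate_snp_effects(M_ref[rec], y_ref[rec], allele_freqs=p, h2=h2)
    weights = window_weights(alpha, S)
    G_w = kinship.weighted_genomic_relationship(M, p, weights)
    K = condition_grm(G_w, ridge) if ridge > 0 else G_w
    res = run_gblup(M_ref, M_cand, y_reference, lam=lam, K=K)
    res.extras["snp_weights"] = weights
    res.extras["alpha_pass1"] = alpha
    return res


def accuracy(gebv: np.ndarray, tbv: np.ndarray, subset: np.ndarray | None = None) -> float:
    """Prediction accuracy: Pearson correlation of GEBV with TBV."""
    gebv = np.asarray(gebv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if subset is not None:
        subset = np.asarray(subset)
        if subset.size == 0:
            raise ValueError("empty evaluation subset")
        gebv, tbv = gebv[subset], tbv[subset]
    if gebv.std() == 0.0 or tbv.std() == 0.0:
        raise ValueError("zero variance in GEBV or TBV")
    return float(np.corrcoef(gebv, tbv)[0, 1])
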