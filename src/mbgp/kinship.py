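"""Pedigree and genomic relationship matrices.

Builds the numerator relationship matrix A (tabular method), its sparse
inverse (Henderson rules with Meuwissen-Luo inbreeding), the VanRaden
genomic relationship matrix G (plain and SNP-weighted), and the combined
single-step inverse H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1].

Pedigrees are passed as integer parent-index arrays: animal i has parents
sire[i], dam[i] (indices into the same ordering, -1 for unknown), and
parents must precede offspring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, splu

__all__ = [
    "numerator_relationship",
    "inbreeding_coefficients",
    "a_inverse",
    "a_submatrix",
    "genomic_relationship",
    "weighted_genomic_relationship",
    "blend_and_align_G",
    "HInverse",
    "h_inverse",
    "SNPWeights",
]


def _check_pedigree(sire: np.ndarray, dam: np.ndarray) -> int:
    sire = np.asarray(sire)
    dam = np.asarray(dam)
    n = len(sire)
    if len(dam) != n:
        raise ValueError("sire and dam arrays must have equal length")
    idx = np.arange(n)
    for par in (sire, dam):
        if np.any(par >= idx):
            raise ValueError("animal listed before its parents")
    return n


def numerator_relationship(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Dense A by the tabular method.

    A_kk = 1 + 0.5 * A_sd, A_kj = 0.5 * (A_js + A_jd); unknown parents
    contribute zero. Quadratic in pedigree size -- intended for reference
    computations and moderate pedigrees.
    """
    n = _check_pedigree(sire, dam)
    A = np.zeros((n, n))
    for k in range(n):
        s, d = sire[k], dam[k]
        if k > 0:
            row = np.zeros(k)
            if s >= 0:
                row += 0.5 * A[s, :k]
            if d >= 0:
                row += 0.5 * A[d, :k]
            A[k, :k] = row
            A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def _mendelian_variance(F: np.ndarray, s: int, d: int) -> float:
    v = 1.0
    if s >= 0:
        v -= 0.25 * (1.0 + F[s])
    if d >= 0:
        v -= 0.25 * (1.0 + F[d])
    return v


def inbreeding_coefficients(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Meuwissen & Luo (1992) inbreeding coefficients F for every animal.

    For each animal, A_ii = sum over its ancestor set of L^2 * D (path
    coefficient squared times Mendelian-sampling variance) and F = A_ii - 1.
    Ancestors are popped youngest-first so each is visited once with its
    accumulated path coefficient.
    """
    n = _check_pedigree(sire, dam)
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    F = np.zeros(n)
    for i in range(n):
        if sire[i] < 0 and dam[i] < 0:
            continue
        stack = {i: 1.0}
        a_ii = 0.0
        while stack:
            a = max(stack)
            coeff = stack.pop(a)
            sa, da = sire[a], dam[a]
            a_ii += coeff * coeff * _mendelian_variance(F, sa, da)
            if sa >= 0:
                stack[sa] = stack.get(sa, 0.0) + 0.5 * coeff
            if da >= 0:
                stack[da] = stack.get(da, 0.0) + 0.5 * coeff
        F[i] = a_ii - 1.0
    return F


def a_inverse(sire: np.ndarray, dam: np.ndarray, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules, with inbreeding if ``F`` is given.

    The Mendelian-sampling variance of animal i is
    d_i = 0.5 - 0.25 (F_s + F_d) with both parents known,
    0.75 - 0.25 F_p with one parent known, and 1 otherwise.
    """
    n = _check_pedigree(sire, dam)
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    if F is None:
        F = np.zeros(n)
    F = np.asarray(F, dtype=float)

    fs = np.where(sire >= 0, F[np.maximum(sire, 0)], -1.0)
    fd = np.where(dam >= 0, F[np.maximum(dam, 0)], -1.0)
    d = 1.0 - 0.25 * (1.0 + fs) * (sire >= 0) - 0.25 * (1.0 + fd) * (dam >= 0)
    alpha = 1.0 / d

    rows, cols, vals = [], [], []
    idx = np.arange(n)

    def add(r, c, v, mask):
        rows.append(r[mask])
        cols.append(c[mask])
        vals.append(v[mask] if np.ndim(v) else np.full(mask.sum(), v))

    has_s, has_d = sire >= 0, dam >= 0
    add(idx, idx, alpha, np.ones(n, bool))
    for par, has in ((sire, has_s), (dam, has_d)):
        add(idx, par, -0.5 * alpha, has)
        add(par, idx, -0.5 * alpha, has)
        add(par, par, 0.25 * alpha, has)
    both = has_s & has_d
    add(sire, dam, 0.25 * alpha, both)
    add(dam, sire, 0.25 * alpha, both)

    A_inv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return A_inv.tocsr()


def a_submatrix(A_inv: sp.spmatrix, idx: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Dense A[idx, idx] recovered from sparse A^-1 by factorised solves."""
    idx = np.asarray(idx, dtype=np.int64)
    n = A_inv.shape[0]
    lu = splu(A_inv.tocsc())
    out = np.empty((len(idx), len(idx)))
    for start in range(0, len(idx), chunk):
        cols = idx[start : start + chunk]
        rhs = np.zeros((n, len(cols)))
        rhs[cols, np.arange(len(cols))] = 1.0
        sol = lu.solve(rhs)
        out[:, start : start + chunk] = sol[idx]
    return 0.5 * (out + out.T)  # symmetrise away factorisation round-off


def _allele_freqs(M: np.ndarray) -> np.ndarray:
    return np.asarray(M, dtype=float).mean(axis=0) / 2.0


def genomic_relationship(
    genotype_matrix: np.ndarray, allele_freqs: np.ndarray | None = None
) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    G = Z Z' / sum_i 2 p_i (1 - p_i) with Z the column-centered 0/1/2
    genotype matrix (Z = M - 2p).
    """
    M = np.asarray(genotype_matrix, dtype=float)
    p = _allele_freqs(M) if allele_freqs is None else np.asarray(allele_freqs, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic marker: allele frequencies must lie in (0, 1)")
    Z = M - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    return (Z @ Z.T) / denom


@dataclass(frozen=True)
class SNPWeights:
    """Diagonal SNP weights for the weighted GRM; mean weight is 1."""

    w: np.ndarray
    window_halfwidth: int
    scaling_constant: float

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if np.any(w < 0):
            raise ValueError("SNP weights must be non-negative")
        object.__setattr__(self, "w", w)


def weighted_genomic_relationship(
    genotype_matrix: np.ndarray,
    allele_freqs: np.ndarray | None,
    weights,
) -> np.ndarray:
    """G_w = Z W Z' / (sum 2 p_i (1-p_i) * mean(w)); W = I recovers plain G."""
    M = np.asarray(genotype_matrix, dtype=float)
    w = weights.w if isinstance(weights, SNPWeights) else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("SNP weights must be non-negative")
    p = _allele_freqs(M) if allele_freqs is None else np.asarray(allele_freqs, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic marker: allele frequencies must lie in (0, 1)")
    Z = M - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p))) * float(np.mean(w))
    return (Z * w) @ Z.T / denom


def blend_and_align_G(G: np.ndarray, A22: np.ndarray, blend_weight: float = 0.95) -> np.ndarray:
    """Scale G's mean diagonal onto A22's, then blend toward A22.

    G* = b * G_scaled + (1 - b) * A22 guarantees an invertible genomic
    relationship for the single-step H matrix.
    """
    if not 0.0 < blend_weight <= 1.0:
        raise ValueError("blend_weight must be in (0, 1]")
    G = np.asarray(G, dtype=float)
    A22 = np.asarray(A22, dtype=float)
    if G.shape != A22.shape:
        raise ValueError("G and A22 dimensions do not match")
    scale = np.mean(np.diag(A22)) / np.mean(np.diag(G))
    return blend_weight * (G * scale) + (1.0 - blend_weight) * A22


class HInverse(LinearOperator):
    """H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1], kept in factored form.

    Stored as the sparse pedigree inverse plus a dense correction on the
    genotyped block, so matrix-vector products stay cheap for large
    pedigrees. ``to_dense`` materialises the full matrix for small cases.
    """

    def __init__(self, A_inv: sp.spmatrix, correction: np.ndarray, genotyped_index: np.ndarray):
        idx = np.asarray(genotyped_index, dtype=np.int64)
        n = A_inv.shape[0]
        if len(idx) and (idx.min() < 0 or idx.max() >= n):
            raise ValueError("genotyped index out of range")
        if correction.shape != (len(idx), len(idx)):
            raise ValueError("correction block not conformable with genotyped index")
        super().__init__(dtype=float, shape=(n, n))
        self.A_inv = A_inv.tocsr()
        self.correction = np.asarray(correction, dtype=float)
        self.genotyped_index = idx

    def _matvec(self, x):
        x = np.asarray(x, dtype=float).ravel()
        y = self.A_inv @ x
        if len(self.genotyped_index):
            y[self.genotyped_index] += self.correction @ x[self.genotyped_index]
        return y

    def _matmat(self, X):
        Y = self.A_inv @ X
        if len(self.genotyped_index):
            Y[self.genotyped_index] += self.correction @ X[self.genotyped_index]
        return Y

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.A_inv.diagonal(), dtype=float).copy()
        if len(self.genotyped_index):
            d[self.genotyped_index] += np.diag(self.correction)
        return d

    def to_dense(self) -> np.ndarray:
        H = self.A_inv.toarray()
        ix = np.ix_(self.genotyped_index, self.genotyped_index)
        H[ix] += self.correction
        return H


def h_inverse(
    A_inv: sp.spmatrix,
    A22_inv: np.ndarray,
    G_star_inv: np.ndarray,
    genotyped_index: np.ndarray,
) -> HInverse:
    """Assemble the single-step inverse from its three ingredients."""
    A22_inv = np.asarray(A22_inv, dtype=float)
    G_star_inv = np.asarray(G_star_inv, dtype=float)
    if A22_inv.shape != G_star_inv.shape:
        raise ValueError("G*^-1 and A22^-1 blocks are not conformable")
    return HInverse(A_inv, G_star_inv - A22_inv, np.asarray(genotyped_index, dtype=np.int64))
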