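"""Marker quality control: missingness, MAF and exact Hardy-Weinberg filters.

Filters mirror the conventional PLINK-style pipeline: individuals with too
many missing calls are dropped first, then markers are screened on call
rate, minor allele frequency (default < 0.05 removed) and the exact
Hardy-Weinberg test (default p < 1e-5 removed). Genotypes are 0/1/2 allele
counts with -1 (or NaN) marking a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = ["QCThresholds", "hwe_exact_pvalue", "hwe_exact_pvalues", "apply_qc_filters", "QCReport"]


@dataclass(frozen=True)
class QCThresholds:
    maf_min: float = 0.05
    locus_missing_max: float = 0.10
    individual_missing_max: float = 0.10
    hwe_p_min: float = 1e-5

    def __post_init__(self):
        for v in (self.maf_min, self.locus_missing_max, self.individual_missing_max, self.hwe_p_min):
            if not 0.0 <= v <= 1.0:
                raise ValueError("QC thresholds must lie in [0, 1]")


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value (Wigginton-style).

    Conditional on the allele counts, sums the probabilities of every
    heterozygote count whose probability does not exceed the observed
    table's. Monomorphic loci return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes observed")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_A, n_a)
    if n_minor == 0:
        return 1.0

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_minor = (n_minor - hets) // 2
    homs_major = (max(n_A, n_a) - hets) // 2
    # log P(het = h | allele counts) up to a common constant
    logp = hets * np.log(2.0) - (
        gammaln(homs_minor + 1) + gammaln(hets + 1) + gammaln(homs_major + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_exact_pvalues(genotypes: np.ndarray) -> np.ndarray:
    """Exact HWE p-value per marker column of a 0/1/2 matrix (missing < 0)."""
    G = np.asarray(genotypes)
    out = np.empty(G.shape[1])
    for j in range(G.shape[1]):
        col = G[:, j]
        col = col[col >= 0]
        out[j] = hwe_exact_pvalue(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
    return out


@dataclass
class QCReport:
    n_individuals_in: int
    n_markers_in: int
    removed_individual_missing: int
    removed_locus_missing: int
    removed_maf: int
    removed_hwe: int

    @property
    def n_individuals_kept(self) -> int:
        return self.n_individuals_in - self.removed_individual_missing

    @property
    def n_markers_kept(self) -> int:
        return (
            self.n_markers_in
            - self.removed_locus_missing
            - self.removed_maf
            - self.removed_hwe
        )

    def to_dict(self) -> dict:
        return dict(self.__dict__, n_markers_kept=self.n_markers_kept,
                    n_individuals_kept=self.n_individuals_kept)


def apply_qc_filters(
    genotypes: np.ndarray,
    thresholds: QCThresholds = QCThresholds(),
    marker_ids: np.ndarray | None = None,
    individual_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, QCReport]:
    """Apply the filters in order: individuals, call rate, MAF, HWE.

    Returns (kept marker ids, kept individual ids, report). Ids default to
    positional indices. Genotype codes: 0/1/2, missing as -1 or NaN.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.size == 0:
        raise ValueError("genotype table is empty")
    n_ind, n_mark = G.shape
    marker_ids = np.arange(n_mark) if marker_ids is None else np.asarray(marker_ids)
    individual_ids = np.arange(n_ind) if individual_ids is None else np.asarray(individual_ids)
    missing = np.isnan(G) | (G < 0)

    ind_keep = missing.mean(axis=1) <= thresholds.individual_missing_max
    G, missing = G[ind_keep], missing[ind_keep]
    n_removed_ind = int((~ind_keep).sum())
    if G.shape[0] == 0:
        raise ValueError("all individuals removed by the missingness filter")

    locus_keep = missing.mean(axis=0) <= thresholds.locus_missing_max
    n_removed_locus = int((~locus_keep).sum())
    G, missing = G[:, locus_keep], missing[:, locus_keep]
    kept = marker_ids[locus_keep]

    with np.errstate(invalid="ignore"):
        p = np.where(missing, np.nan, G)
        freq = np.nanmean(p, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    maf_keep = maf >= thresholds.maf_min
    n_removed_maf = int((~maf_keep).sum())
    G, missing, kept = G[:, maf_keep], missing[:, maf_keep], kept[maf_keep]

    Gi = np.where(missing, -1, G).astype(int)
    pvals = hwe_exact_pvalues(Gi)
    hwe_keep = pvals >= thresholds.hwe_p_min
    n_removed_hwe = int((~hwe_keep).sum())
    kept = kept[hwe_keep]

    report = QCReport(
        n_individuals_in=n_ind,
        n_markers_in=n_mark,
        removed_individual_missing=n_removed_ind,
        removed_locus_missing=n_removed_locus,
        removed_maf=n_removed_maf,
        removed_hwe=n_removed_hwe,
    )
    return kept, individual_ids[ind_keep], report
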