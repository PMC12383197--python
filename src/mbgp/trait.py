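"""Additive trait model: QTL effects, true breeding values, phenotypes.

A single quantitative trait is controlled by additive QTL effects drawn
from a gamma distribution (shape 0.4, random sign) and rescaled so the
base population's true-breeding-value variance equals the target additive
variance (0.42 under the default settings, giving h^2 = 0.42 at phenotypic
variance 1.0). Phenotypes are TBV plus independent Gaussian residuals;
records go missing with a fixed probability (0.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TraitModel", "draw_qtl_effects", "true_breeding_value", "simulate_phenotype"]


@dataclass(frozen=True)
class TraitModel:
    qtl_effects: np.ndarray
    sigma_a2: float
    sigma_e2: float
    mu: float = 0.0

    @property
    def heritability(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)

    @property
    def lambda_ratio(self) -> float:
        """Variance ratio sigma_e^2 / sigma_a^2 used in the mixed-model equations."""
        return self.sigma_e2 / self.sigma_a2

    def to_frame(self, genome_map=None) -> pd.DataFrame:
        df = pd.DataFrame({"qtl": np.arange(len(self.qtl_effects)), "effect": self.qtl_effects})
        if genome_map is not None:
            idx = genome_map.qtl_index
            df["chromosome"] = genome_map.locus_chrom[idx]
            df["position_cM"] = genome_map.locus_pos_cM[idx]
        return df


def draw_qtl_effects(
    n_qtl: int,
    gamma_shape: float,
    target_sigma_a2: float,
    base_population_qtl_genotypes: np.ndarray,
    rng: np.random.Generator,
    sigma_e2: float | None = None,
    phenotypic_variance: float = 1.0,
) -> TraitModel:
    """Draw signed gamma QTL effects calibrated to the target additive variance.

    Effect magnitudes are gamma(shape) draws, signs are fair coins, and one
    global rescaling constant makes the variance of TBV over the supplied
    base-population genotypes exactly ``target_sigma_a2``.
    """
    if n_qtl < 1:
        raise ValueError("n_qtl must be >= 1")
    Q = np.asarray(base_population_qtl_genotypes, dtype=float)
    if Q.ndim != 2 or Q.shape[1] != n_qtl:
        raise ValueError("base genotypes must be (n_animals, n_qtl)")

    raw = rng.gamma(gamma_shape, 1.0, size=n_qtl)
    raw *= rng.choice([-1.0, 1.0], size=n_qtl)
    if target_sigma_a2 == 0.0:
        effects = np.zeros(n_qtl)
    else:
        tbv = Q @ raw
        v = float(np.var(tbv))
        if v <= 1e-12 * max(1.0, float(np.mean(tbv**2))):
            raise ValueError("base-population TBV variance is zero (all QTL fixed)")
        effects = raw * np.sqrt(target_sigma_a2 / v)
    if sigma_e2 is None:
        sigma_e2 = phenotypic_variance - target_sigma_a2
    if sigma_e2 < 0:
        raise ValueError("residual variance must be non-negative")
    return TraitModel(qtl_effects=effects, sigma_a2=float(target_sigma_a2), sigma_e2=float(sigma_e2))


def true_breeding_value(qtl_genotypes: np.ndarray, qtl_effects: np.ndarray) -> np.ndarray:
    """TBV_k = sum_j beta_j * Q_kj with Q in {0, 1, 2} allele copies."""
    Q = np.asarray(qtl_genotypes)
    if not np.isin(Q, (0, 1, 2)).all():
        raise ValueError("QTL genotype codes must be in {0, 1, 2}")
    return Q.astype(float) @ np.asarray(qtl_effects, dtype=float)


def simulate_phenotype(
    tbv: np.ndarray,
    mu: float,
    sigma_e2: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """y = mu + TBV + N(0, sigma_e2); missing records are NaN."""
    if sigma_e2 < 0:
        raise ValueError("sigma_e2 must be non-negative")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    tbv = np.asarray(tbv, dtype=float)
    y = mu + tbv + rng.normal(0.0, np.sqrt(sigma_e2), size=tbv.shape)
    if missing_rate > 0:
        y = np.where(rng.random(tbv.shape) < missing_rate, np.nan, y)
    return y
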