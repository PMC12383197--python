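"""Simulated genome: marker/QTL map, meiosis and recurrent mutation.

The genome is a set of autosomes carrying biallelic loci of two kinds,
neutral SNP markers and QTL. Loci live on a genetic map (centimorgans);
recombination is modelled as a Poisson process along each chromosome
(mean one crossover per Morgan) and mutation is recurrent, i.e. an allele
flips to the other state and never creates a third allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeMap", "build_genome", "largest_remainder", "sample_gamete", "sample_gametes"]


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Allocate ``total`` integer counts proportionally to ``weights``.

    Uses largest-remainder (Hamilton) rounding; ties go to the lower index.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("allocation weights must be positive")
    shares = total * weights / weights.sum()
    counts = np.floor(shares).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        order = np.argsort(-(shares - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


@dataclass(frozen=True)
class GenomeMap:
    """Positions and states of every locus in the simulated genome.

    Loci are stored in a single array sorted by (chromosome, position) so a
    haplotype is one vector over all loci; ``is_qtl`` flags the QTL subset.
    """

    chrom_lengths_cM: np.ndarray
    locus_chrom: np.ndarray
    locus_pos_cM: np.ndarray
    is_qtl: np.ndarray
    mutation_rate: float = 2.5e-5

    def __post_init__(self) -> None:
        for name in ("chrom_lengths_cM", "locus_chrom", "locus_pos_cM", "is_qtl"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if np.any(self.chrom_lengths_cM <= 0):
            raise ValueError("chromosome lengths must be positive")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must be a probability")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths_cM)

    @property
    def n_loci(self) -> int:
        return len(self.locus_pos_cM)

    @property
    def n_markers(self) -> int:
        return int((~self.is_qtl).sum())

    @property
    def n_qtl(self) -> int:
        return int(self.is_qtl.sum())

    @property
    def total_length_cM(self) -> float:
        return float(self.chrom_lengths_cM.sum())

    @property
    def marker_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    def chrom_slices(self) -> list[slice]:
        """Contiguous locus slice per chromosome."""
        bounds = np.searchsorted(self.locus_chrom, np.arange(self.n_chromosomes + 1))
        return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    def marker_table(self):
        """(chromosome, cM position) of markers, in map order."""
        idx = self.marker_index
        return self.locus_chrom[idx], self.locus_pos_cM[idx]


def build_genome(
    n_chromosomes: int,
    chrom_lengths_cM,
    n_markers: int,
    n_qtl: int,
    rng: np.random.Generator,
    mutation_rate: float = 2.5e-5,
) -> GenomeMap:
    """Lay out a genome with uniformly placed markers and QTL.

    Marker (and QTL) counts per chromosome are proportional to map length,
    rounded by the largest-remainder rule; positions are uniform within the
    chromosome. Marker and QTL positions are almost surely distinct
    (continuous draws); shared positions are re-drawn.
    """
    lengths = np.asarray(chrom_lengths_cM, dtype=float)
    if len(lengths) != n_chromosomes:
        raise ValueError("chrom_lengths_cM length must equal n_chromosomes")
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be positive")
    if n_qtl < 0:
        raise ValueError("n_qtl must be non-negative")
    if n_markers < n_chromosomes:
        raise ValueError("need at least one marker per chromosome")

    m_counts = largest_remainder(lengths, n_markers)
    q_counts = largest_remainder(lengths, n_qtl) if n_qtl > 0 else np.zeros(n_chromosomes, int)

    chroms, positions, qtl_flags = [], [], []
    for c in range(n_chromosomes):
        n_m, n_q = int(m_counts[c]), int(q_counts[c])
        pos = rng.uniform(0.0, lengths[c], size=n_m + n_q)
        while len(np.unique(pos)) < len(pos):  # pragma: no cover - measure-zero event
            pos = rng.uniform(0.0, lengths[c], size=n_m + n_q)
        flag = np.zeros(n_m + n_q, dtype=bool)
        flag[rng.choice(n_m + n_q, size=n_q, replace=False)] = True
        order = np.argsort(pos)
        chroms.append(np.full(n_m + n_q, c))
        positions.append(pos[order])
        qtl_flags.append(flag[order])

    return GenomeMap(
        chrom_lengths_cM=lengths,
        locus_chrom=np.concatenate(chroms),
        locus_pos_cM=np.concatenate(positions),
        is_qtl=np.concatenate(qtl_flags),
        mutation_rate=mutation_rate,
    )


def sample_gametes(
    parent_haplotypes: np.ndarray,
    genome_map: GenomeMap,
    rng: np.random.Generator,
    mutate: bool = True,
    return_diagnostics: bool = False,
):
    """Draw one recombinant gamete per parent.

    ``parent_haplotypes`` has shape (n, 2, n_loci). Per chromosome the
    crossover count is Poisson(length in Morgans), breakpoints are uniform,
    and copying starts from a fair-coin haplotype. Afterwards each allele
    flips independently with the map's recurrent mutation rate.

    With ``return_diagnostics`` also returns (crossover count, mutation
    count) per gamete, for rate calibration.
    """
    haps = np.asarray(parent_haplotypes)
    if haps.ndim != 3 or haps.shape[1] != 2 or haps.shape[2] != genome_map.n_loci:
        raise ValueError("parent_haplotypes must have shape (n, 2, n_loci)")
    n = haps.shape[0]
    gamete = np.empty((n, genome_map.n_loci), dtype=haps.dtype)
    rows = np.arange(n)[:, None]
    total_crossovers = np.zeros(n, dtype=np.int64)

    for c, sl in enumerate(genome_map.chrom_slices()):
        length_morgan = genome_map.chrom_lengths_cM[c] / 100.0
        pos = genome_map.locus_pos_cM[sl]
        n_x = rng.poisson(length_morgan, size=n)
        total_crossovers += n_x
        start = rng.integers(0, 2, size=n)
        k_max = int(n_x.max()) if n > 0 else 0
        if k_max == 0:
            choice = np.broadcast_to(start[:, None], (n, len(pos)))
        else:
            bp = rng.uniform(0.0, genome_map.chrom_lengths_cM[c], size=(n, k_max))
            bp[np.arange(k_max)[None, :] >= n_x[:, None]] = np.inf
            crossings = (bp[:, :, None] < pos[None, None, :]).sum(axis=1)
            choice = (start[:, None] + crossings) % 2
        gamete[:, sl] = haps[rows, choice, np.arange(sl.start, sl.stop)[None, :]]

    n_mutations = np.zeros(n, dtype=np.int64)
    if mutate and genome_map.mutation_rate > 0:
        flips = rng.random(gamete.shape) < genome_map.mutation_rate
        gamete ^= flips.astype(gamete.dtype)
        n_mutations = flips.sum(axis=1)
    if return_diagnostics:
        return gamete, total_crossovers, n_mutations
    return gamete


def sample_gamete(
    parent_haplotype_pair: np.ndarray,
    genome_map: GenomeMap,
    rng: np.random.Generator,
    mutate: bool = True,
) -> np.ndarray:
    """Single-parent convenience wrapper around :func:`sample_gametes`."""
    return sample_gametes(np.asarray(parent_haplotype_pair)[None], genome_map, rng, mutate)[0]
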