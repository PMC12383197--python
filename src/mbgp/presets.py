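"""Study presets: genome, demographies and breeding schemes for PopA/B/C.

Three named scales share one structure:

* ``full``   -- the full study scale (29 autosomes, 2715.85 cM, 58,990
  markers, 725 QTL, a 1000-generation ancestral trunk, censuses in the
  thousands). Hours of compute per replicate; run it via the CLI.
* ``desk``   -- the routine working scale: 3 chromosomes (300 cM), 9,000
  markers, 75 QTL, shorter histories and censuses divided by five.
  Under a minute per replicate; used by the acceptance pipeline.
* ``micro``  -- a further-reduced scale for repeated statistical checks.

The three breeds of a replicate descend from one ancestral *trunk*
population (simulated to build up mutation-drift-equilibrium LD and
shared polymorphism), then diverge along breed-specific *branch* size
schedules -- PopA stays small and then expands (slowest LD decay), PopB
shrinks then recovers, PopC stays large and contracts late (fastest LD
decay). A recent divergence (~100 generations at the full scale, as for
real cattle breeds) is what lets marker-QTL phase transfer across breeds
at short range; fully independent histories would share neither
polymorphism nor LD phase. The genome map and the QTL-effect vector are
common to the three breeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GenomeMap, build_genome
from .simulate import BreedingScheme, DemographyPhase

__all__ = ["PopulationDesign", "SimulationPreset", "get_preset", "PRESETS"]

# approximate physical sizes (Mb) of the 29 cattle autosomes, used only as
# relative weights for chromosome map lengths
_CATTLE_AUTOSOME_MB = np.array(
    [158.5, 136.2, 121.0, 120.8, 120.1, 117.8, 110.7, 113.4, 105.7, 103.3,
     106.3, 87.2, 83.5, 82.4, 85.0, 81.0, 73.2, 65.8, 63.4, 71.9,
     69.9, 60.7, 52.5, 62.3, 42.4, 51.7, 45.6, 45.9, 51.1]
)


@dataclass(frozen=True)
class PopulationDesign:
    name: str
    phases: tuple[DemographyPhase, ...]
    scheme: BreedingScheme


@dataclass(frozen=True)
class SimulationPreset:
    name: str
    chrom_lengths_cM: tuple[float, ...]
    n_markers: int
    n_qtl: int
    trunk_phases: tuple[DemographyPhase, ...]
    populations: dict[str, PopulationDesign]
    mutation_rate: float = 2.5e-5
    gamma_shape: float = 0.4
    h2: float = 0.42
    phenotypic_variance: float = 1.0

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths_cM)

    @property
    def sigma_a2(self) -> float:
        return self.h2 * self.phenotypic_variance

    @property
    def sigma_e2(self) -> float:
        return self.phenotypic_variance - self.sigma_a2

    def build_genome(self, rng: np.random.Generator) -> GenomeMap:
        return build_genome(
            self.n_chromosomes,
            np.asarray(self.chrom_lengths_cM),
            self.n_markers,
            self.n_qtl,
            rng,
            mutation_rate=self.mutation_rate,
        )


def _scheme(exp_m, exp_f, found_m, found_f, repl_s, repl_d, exp_gens=10, sel_gens=10):
    return BreedingScheme(
        expansion_males=exp_m,
        expansion_females=exp_f,
        expansion_generations=exp_gens,
        n_founder_males=found_m,
        n_founder_females=found_f,
        selected_generations=sel_gens,
        sire_replacement=repl_s,
        dam_replacement=repl_d,
    )


def _phases(*triples):
    return tuple(DemographyPhase(n_generations=g, start_size=a, end_size=b) for g, a, b in triples)


def _full_preset() -> SimulationPreset:
    lengths = tuple(_CATTLE_AUTOSOME_MB / _CATTLE_AUTOSOME_MB.sum() * 2715.85)
    pops = {
        # stable and small post-divergence, then expansion to 1000
        "A": PopulationDesign("A", _phases((100, 200, 200), (95, 200, 1000)),
                              _scheme(250, 3000, 200, 2800, 0.6, 0.3)),
        # decline 500 -> 200, then expansion to 1000
        "B": PopulationDesign("B", _phases((100, 500, 200), (95, 200, 1000)),
                              _scheme(250, 2550, 220, 2335, 0.5, 0.3)),
        # stays large, late contraction to 200
        "C": PopulationDesign("C", _phases((100, 1000, 1000), (95, 1000, 200)),
                              _scheme(250, 3000, 200, 2800, 0.5, 0.2)),
    }
    return SimulationPreset(
        name="full",
        chrom_lengths_cM=lengths,
        n_markers=58_990,
        n_qtl=725,
        trunk_phases=_phases((1000, 1000, 1000)),
        populations=pops,
    )


def _desk_preset() -> SimulationPreset:
    pops = {
        "A": PopulationDesign("A", _phases((40, 40, 40), (19, 40, 200)),
                              _scheme(50, 600, 40, 560, 0.6, 0.3)),
        "B": PopulationDesign("B", _phases((40, 100, 40), (19, 40, 200)),
                              _scheme(50, 510, 44, 467, 0.5, 0.3)),
        "C": PopulationDesign("C", _phases((40, 200, 200), (19, 200, 40)),
                              _scheme(50, 600, 40, 560, 0.5, 0.2)),
    }
    # 30 markers/cM: cross-breed genomic relationships are estimated from the
    # markers polymorphic in every breed; the panel must stay dense enough
    # after drift losses for that block of G to carry signal rather than
    # sampling noise (see docs/methods.md on the shared-marker regime)
    return SimulationPreset(
        name="desk",
        chrom_lengths_cM=(120.0, 100.0, 80.0),
        n_markers=9000,
        n_qtl=75,
        trunk_phases=_phases((200, 120, 120)),
        populations=pops,
    )


def _micro_preset() -> SimulationPreset:
    pops = {
        "A": PopulationDesign("A", _phases((15, 30, 30), (8, 30, 100)),
                              _scheme(25, 300, 20, 280, 0.6, 0.3, exp_gens=5, sel_gens=5)),
        "B": PopulationDesign("B", _phases((15, 60, 30), (8, 30, 100)),
                              _scheme(25, 255, 22, 234, 0.5, 0.3, exp_gens=5, sel_gens=5)),
        "C": PopulationDesign("C", _phases((15, 120, 120), (8, 120, 40)),
                              _scheme(25, 300, 20, 280, 0.5, 0.2, exp_gens=5, sel_gens=5)),
    }
    return SimulationPreset(
        name="micro",
        chrom_lengths_cM=(100.0, 100.0),
        n_markers=800,
        n_qtl=40,
        trunk_phases=_phases((60, 60, 60)),
        populations=pops,
    )


PRESETS = {"full": _full_preset, "desk": _desk_preset, "micro": _micro_preset}


def get_preset(name: str) -> SimulationPreset:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
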