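"""Forward-in-time simulation of breeding populations.

Two phases mirror a conventional two-phase livestock breeding-simulation design:

* a *historical* phase of random mating (Wright-Fisher random union of
  gametes, equal sex ratio, non-overlapping generations, no selection)
  whose census follows a piecewise-linear size schedule -- this is what
  shapes each population's linkage-disequilibrium decay; and
* a *recent* phase with an expansion stage (random mating, litter size 1)
  followed by a selection stage in which a fixed breeding set is truncated
  on pedigree-BLUP EBV: every generation the stated replacement fraction
  of sires/dams is culled (lowest EBV first, older animals first on ties)
  and replaced by the top-EBV young animals.

Genotypes and phenotypes are retained only for the last two recent
generations ("generation 9" and "generation 10" at the study scale);
pedigree, true breeding values and inbreeding are kept for all recent
animals so the pedigree relationship matrix can be built exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeMap, sample_gametes
from .trait import TraitModel, simulate_phenotype, true_breeding_value

__all__ = [
    "DemographyPhase",
    "BreedingScheme",
    "Population",
    "census_schedule",
    "run_historical",
    "run_recent",
    "KinshipTracker",
]

MALE, FEMALE = 1, 2


@dataclass(frozen=True)
class DemographyPhase:
    """One historical phase: census interpolates linearly between endpoints."""

    n_generations: int
    start_size: int
    end_size: int

    def __post_init__(self):
        if self.start_size < 2 or self.end_size < 2:
            raise ValueError("population sizes must be >= 2")
        if self.n_generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass(frozen=True)
class BreedingScheme:
    """Recent-phase design: expansion censuses, breeding-set sizes, turnover."""

    expansion_males: int
    expansion_females: int
    expansion_generations: int
    n_founder_males: int
    n_founder_females: int
    selected_generations: int
    sire_replacement: float
    dam_replacement: float
    litter_size: int = 1
    selection_criterion: str = "ebv"
    culling_criterion: str = "ebv"
    missing_record_rate: float = 0.05

    def __post_init__(self):
        for r in (self.sire_replacement, self.dam_replacement):
            if not 0.0 <= r <= 1.0:
                raise ValueError("replacement fractions must be in [0, 1]")
        if self.litter_size != 1:
            raise ValueError("litter size is 1 in this design")
        if self.selection_criterion not in ("ebv", "phenotype"):
            raise ValueError("selection_criterion must be 'ebv' or 'phenotype'")


@dataclass
class Population:
    """Pedigreed animals with (partially retained) haplotypes.

    ``pedigree`` has one row per animal: id (1-based), sire, dam (0 =
    unknown), sex (1 = male, 2 = female), generation, F (inbreeding),
    tbv, phenotype (NaN = missing/unrecorded), ebv (NaN = never
    estimated). ``haplotypes`` covers the subset listed in
    ``haplotype_ids`` (sorted ascending).
    """

    pedigree: pd.DataFrame
    haplotypes: np.ndarray
    haplotype_ids: np.ndarray
    genome: GenomeMap
    meta: dict = field(default_factory=dict)

    def hap_rows(self, ids: np.ndarray) -> np.ndarray:
        ids = np.asarray(ids)
        rows = np.searchsorted(self.haplotype_ids, ids)
        if np.any(rows >= len(self.haplotype_ids)) or np.any(self.haplotype_ids[rows] != ids):
            raise KeyError("haplotypes not retained for some requested animals")
        return rows

    def genotypes(self, ids: np.ndarray | None = None, loci: np.ndarray | None = None) -> np.ndarray:
        haps = self.haplotypes if ids is None else self.haplotypes[self.hap_rows(ids)]
        g = haps.sum(axis=1, dtype=np.int16)
        return g if loci is None else g[:, loci]

    def marker_genotypes(self, ids: np.ndarray | None = None) -> np.ndarray:
        return self.genotypes(ids, self.genome.marker_index)

    def qtl_genotypes(self, ids: np.ndarray | None = None) -> np.ndarray:
        return self.genotypes(ids, self.genome.qtl_index)

    def generation_ids(self, generation: int) -> np.ndarray:
        ped = self.pedigree
        return ped.loc[ped["generation"] == generation, "id"].to_numpy()


def census_schedule(phases: list[DemographyPhase]) -> np.ndarray:
    """Census per generation (generation 0 included), linear within phases."""
    if not phases:
        raise ValueError("at least one demography phase is required")
    sizes = [phases[0].start_size]
    for k, ph in enumerate(phases):
        if k > 0 and ph.start_size != phases[k - 1].end_size:
            raise ValueError("phase sizes inconsistent at junction")
        for t in range(1, ph.n_generations + 1):
            frac = t / ph.n_generations
            sizes.append(int(round(ph.start_size + frac * (ph.end_size - ph.start_size))))
    return np.asarray(sizes, dtype=int)


def _split_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Equal sex ratio, enforced exactly (n//2 males), randomly placed."""
    if n < 2:
        raise ValueError("cannot split fewer than two animals into sexes")
    sexes = np.full(n, FEMALE, dtype=np.int8)
    sexes[: n // 2] = MALE
    return rng.permutation(sexes)


def _founder_haplotypes(
    n: int, genome_map: GenomeMap, rng: np.random.Generator, founder_pool: np.ndarray | None
) -> np.ndarray:
    if founder_pool is None:
        return (rng.random((n, 2, genome_map.n_loci)) < 0.5).astype(np.uint8)
    picks = rng.integers(0, len(founder_pool), size=2 * n)
    return founder_pool[picks].reshape(n, 2, genome_map.n_loci)


def run_historical(
    genome_map: GenomeMap,
    phases: list[DemographyPhase],
    rng: np.random.Generator,
    founder_pool: np.ndarray | None = None,
) -> Population:
    """Random-mating history along a census schedule; returns the final generation.

    Founder haplotypes are i.i.d. Bernoulli(0.5) alleles (equal starting
    frequencies) unless ``founder_pool`` -- an array of haplotypes shared
    across populations to model common ancestry -- is given, in which case
    generation-0 haplotypes are drawn from the pool with replacement.
    Each offspring's parents are drawn uniformly with replacement (random
    union of gametes), so drift matches Wright-Fisher expectations.
    """
    schedule = census_schedule(phases)
    haps = _founder_haplotypes(schedule[0], genome_map, rng, founder_pool)
    sexes = _split_sexes(schedule[0], rng)

    for n_next in schedule[1:]:
        males = np.flatnonzero(sexes == MALE)
        females = np.flatnonzero(sexes == FEMALE)
        if len(males) == 0 or len(females) == 0:
            raise RuntimeError("historical generation lost one sex entirely")
        sires = rng.choice(males, size=n_next, replace=True)
        dams = rng.choice(females, size=n_next, replace=True)
        paternal = sample_gametes(haps[sires], genome_map, rng)
        maternal = sample_gametes(haps[dams], genome_map, rng)
        haps = np.stack([paternal, maternal], axis=1)
        sexes = _split_sexes(n_next, rng)

    n = len(haps)
    ped = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sire": 0,
            "dam": 0,
            "sex": sexes,
            "generation": 0,
            "F": 0.0,
            "tbv": np.nan,
            "phenotype": np.nan,
            "ebv": np.nan,
        }
    )
    return Population(
        pedigree=ped,
        haplotypes=haps,
        haplotype_ids=np.arange(1, n + 1),
        genome=genome_map,
        meta={"phase": "historical", "schedule": schedule},
    )


class KinshipTracker:
    """Incremental coancestry among the animals still relevant to breeding.

    Keeps the coancestry (kinship) matrix f for an active set of animals;
    offspring rows are derived from parent rows by the standard recursions
    f(o, x) = (f(s, x) + f(d, x)) / 2 and f(o, o) = (1 + f(s, d)) / 2, so
    each newborn's inbreeding coefficient F = f(sire, dam) is exact.
    """

    def __init__(self, ids: np.ndarray, F: np.ndarray | None = None):
        self.ids = np.asarray(ids, dtype=np.int64)
        n = len(self.ids)
        f0 = 0.5 * (1.0 + (np.zeros(n) if F is None else np.asarray(F, dtype=float)))
        self.f = np.diag(f0)
        self._pos = {int(i): k for k, i in enumerate(self.ids)}

    def positions(self, ids: np.ndarray) -> np.ndarray:
        return np.fromiter((self._pos[int(i)] for i in ids), dtype=np.int64, count=len(ids))

    def add_offspring(self, offspring_ids: np.ndarray, sire_ids: np.ndarray, dam_ids: np.ndarray) -> np.ndarray:
        """Append offspring; returns their inbreeding coefficients."""
        s = self.positions(sire_ids)
        d = self.positions(dam_ids)
        F_new = self.f[s, d]
        R = 0.5 * (self.f[s, :] + self.f[d, :])  # offspring x active
        O = 0.5 * (R[:, s] + R[:, d])  # offspring x offspring
        np.fill_diagonal(O, 0.5 * (1.0 + F_new))
        n_old = len(self.ids)
        n_new = len(offspring_ids)
        f = np.empty((n_old + n_new, n_old + n_new))
        f[:n_old, :n_old] = self.f
        f[n_old:, :n_old] = R
        f[:n_old, n_old:] = R.T
        f[n_old:, n_old:] = O
        self.f = f
        self.ids = np.concatenate([self.ids, np.asarray(offspring_ids, dtype=np.int64)])
        for k, i in enumerate(offspring_ids, start=n_old):
            self._pos[int(i)] = k
        return F_new

    def keep(self, ids: np.ndarray) -> None:
        pos = self.positions(np.asarray(ids))
        self.f = self.f[np.ix_(pos, pos)]
        self.ids = self.ids[pos]
        self._pos = {int(i): k for k, i in enumerate(self.ids)}

    def coancestry(self, ids_a: np.ndarray, ids_b: np.ndarray) -> np.ndarray:
        return self.f[np.ix_(self.positions(ids_a), self.positions(ids_b))]


class _RecentState:
    """Columnar pedigree under construction plus haplotype bookkeeping."""

    def __init__(self, genome: GenomeMap):
        self.genome = genome
        self.id, self.sire, self.dam = [], [], []
        self.sex, self.generation = [], []
        self.F, self.tbv, self.phen = [], [], []
        self.haps: dict[int, np.ndarray] = {}  # id -> (2, L); pruned as cohorts expire

    def n(self) -> int:
        return len(self.id)

    def add_cohort(self, sire_ids, dam_ids, sexes, generation, F, tbv, phen, haps) -> np.ndarray:
        start = self.n() + 1
        ids = np.arange(start, start + len(sexes))
        self.id.extend(ids)
        self.sire.extend(np.asarray(sire_ids, dtype=int))
        self.dam.extend(np.asarray(dam_ids, dtype=int))
        self.sex.extend(sexes)
        self.generation.extend([generation] * len(sexes))
        self.F.extend(F)
        self.tbv.extend(tbv)
        self.phen.extend(phen)
        for i, h in zip(ids, haps):
            self.haps[int(i)] = h
        return ids

    def gather_haps(self, ids: np.ndarray) -> np.ndarray:
        return np.stack([self.haps[int(i)] for i in ids])

    def prune_haps(self, keep_ids: set[int]) -> None:
        for i in list(self.haps):
            if i not in keep_ids:
                del self.haps[i]


def _score(state: _RecentState, ebv: np.ndarray, criterion: str) -> np.ndarray:
    if criterion == "ebv":
        return ebv
    y = np.asarray(state.phen, dtype=float)
    return np.where(np.isnan(y), -np.inf, y)


def _default_pblup_hook(lam: float):
    from .models import run_pblup

    def hook(sire_idx, dam_idx, F, record_rows, y, _lam=lam):
        res = run_pblup(sire_idx, dam_idx, record_rows, y, lam=_lam, F=F, tolerance=1e-8)
        return res.gebv

    return hook


def run_recent(
    founders: Population,
    scheme: BreedingScheme,
    trait_model: TraitModel,
    rng: np.random.Generator,
    evaluator_hook=None,
) -> Population:
    """Expansion then EBV-truncation selection; see module docstring.

    ``evaluator_hook(sire_idx, dam_idx, F, record_rows, y_records)`` must
    return an EBV for every pedigree animal; the default is pedigree BLUP
    at the trait model's variance ratio.
    """
    gm = founders.genome
    qtl = gm.qtl_index
    beta = trait_model.qtl_effects
    if evaluator_hook is None:
        evaluator_hook = _default_pblup_hook(trait_model.lambda_ratio)

    state = _RecentState(gm)
    # generation 0: the historical final generation becomes the pedigree base
    n_f = len(founders.pedigree)
    founder_tbv = true_breeding_value(founders.qtl_genotypes(), beta)
    state.add_cohort(
        sire_ids=np.zeros(n_f, int),
        dam_ids=np.zeros(n_f, int),
        sexes=founders.pedigree["sex"].to_numpy(),
        generation=0,
        F=np.zeros(n_f),
        tbv=founder_tbv,
        phen=np.full(n_f, np.nan),
        haps=founders.haplotypes,
    )
    founder_ids = np.arange(1, n_f + 1)
    tracker = KinshipTracker(founder_ids)

    def make_offspring(sire_ids, dam_ids, generation):
        pat = sample_gametes(state.gather_haps(sire_ids), gm, rng)
        mat = sample_gametes(state.gather_haps(dam_ids), gm, rng)
        haps = np.stack([pat, mat], axis=1)
        sexes = _split_sexes(len(haps), rng)
        tbv = true_breeding_value(haps[:, 0, qtl] + haps[:, 1, qtl], beta)
        phen = simulate_phenotype(
            tbv, trait_model.mu, trait_model.sigma_e2, scheme.missing_record_rate, rng
        )
        start = state.n() + 1
        ids = np.arange(start, start + len(haps))
        F_new = tracker.add_offspring(ids, sire_ids, dam_ids)
        state.add_cohort(sire_ids, dam_ids, sexes, generation, F_new, tbv, phen, haps)
        return ids

    def sample_pool(candidate_ids, size, rng):
        if size <= len(candidate_ids):
            return rng.choice(candidate_ids, size=size, replace=False)
        return candidate_ids  # fewer available than requested: use all, reuse in mating

    sex_arr = lambda ids: np.asarray(state.sex, dtype=int)[np.asarray(ids) - 1]

    # ---- stage 1: expansion by random mating -------------------------------
    cohort = founder_ids
    prev_cohort = founder_ids
    for g in range(1, scheme.expansion_generations + 1):
        sexes = sex_arr(cohort)
        male_pool = sample_pool(cohort[sexes == MALE], scheme.expansion_males, rng)
        female_pool = cohort[sexes == FEMALE]
        n_off = scheme.expansion_females * scheme.litter_size
        if len(female_pool) >= n_off:
            dams = rng.choice(female_pool, size=n_off, replace=False)
        else:
            dams = rng.choice(female_pool, size=n_off, replace=True)
        sires = rng.choice(male_pool, size=n_off, replace=True)
        new_ids = make_offspring(sires, dams, g)
        # only the last two cohorts can still become parents or founders
        tracker.keep(np.concatenate([cohort, new_ids]))
        state.prune_haps(set(int(i) for i in np.concatenate([cohort, new_ids])))
        prev_cohort, cohort = cohort, new_ids

    # ---- stage 2: truncation selection on EBV ------------------------------
    pool = np.unique(np.concatenate([prev_cohort, cohort]))
    pool_sex = sex_arr(pool)
    pool_m, pool_f = pool[pool_sex == MALE], pool[pool_sex == FEMALE]
    if len(pool_m) < scheme.n_founder_males or len(pool_f) < scheme.n_founder_females:
        raise RuntimeError("expansion stage too small to supply the breeding founders")
    sires_breeding = rng.choice(pool_m, size=scheme.n_founder_males, replace=False)
    dams_breeding = rng.choice(pool_f, size=scheme.n_founder_females, replace=False)

    n_cull_s = int(np.floor(scheme.sire_replacement * len(sires_breeding) + 0.5))
    n_cull_d = int(np.floor(scheme.dam_replacement * len(dams_breeding) + 0.5))
    retained: list[np.ndarray] = []
    ebv = np.full(state.n(), np.nan)

    for g in range(1, scheme.selected_generations + 1):
        generation = scheme.expansion_generations + g
        breeding = np.concatenate([sires_breeding, dams_breeding])
        keep_ids = np.unique(np.concatenate([breeding] + retained)) if retained else breeding
        tracker.keep(keep_ids)
        state.prune_haps(set(int(i) for i in keep_ids))
        dams = rng.permutation(dams_breeding)  # each dam exactly one offspring
        sires = rng.choice(sires_breeding, size=len(dams), replace=True)
        new_ids = make_offspring(sires, dams, generation)
        if g >= scheme.selected_generations - 1:
            retained.append(new_ids)

        # EBV for everyone, then replace the worst breeders with the best young
        rows = np.arange(state.n())
        gen_arr = np.asarray(state.generation)
        y_all = np.asarray(state.phen, dtype=float)
        rec = rows[(gen_arr >= 1) & ~np.isnan(y_all)]
        ebv = evaluator_hook(
            np.asarray(state.sire, int) - 1,
            np.asarray(state.dam, int) - 1,
            np.asarray(state.F, float),
            rec,
            y_all[rec],
        )
        if g == scheme.selected_generations:
            break
        score = _score(state, ebv, scheme.selection_criterion)
        new_sexes = sex_arr(new_ids)
        for is_male, n_cull in ((True, n_cull_s), (False, n_cull_d)):
            group = sires_breeding if is_male else dams_breeding
            if n_cull == 0:
                continue
            order = np.lexsort((group, gen_arr[group - 1], score[group - 1]))
            culled = set(group[order[:n_cull]].tolist())
            young = new_ids[new_sexes == (MALE if is_male else FEMALE)]
            if len(young) < n_cull:
                raise RuntimeError("replacement demand exceeds available young animals")
            yorder = np.lexsort((young, -score[young - 1]))
            recruits = young[yorder[:n_cull]]
            kept = np.array([a for a in group if a not in culled], dtype=np.int64)
            group_new = np.concatenate([kept, recruits])
            if is_male:
                sires_breeding = group_new
            else:
                dams_breeding = group_new

    # ---- assemble the output population ------------------------------------
    gen_arr = np.asarray(state.generation)
    last_two = set(
        int(g)
        for g in (
            scheme.expansion_generations + scheme.selected_generations - 1,
            scheme.expansion_generations + scheme.selected_generations,
        )
    )
    phen = np.asarray(state.phen, dtype=float)
    phen[~np.isin(gen_arr, list(last_two))] = np.nan  # records retained for gens 9-10 only

    ped = pd.DataFrame(
        {
            "id": np.asarray(state.id, int),
            "sire": np.asarray(state.sire, int),
            "dam": np.asarray(state.dam, int),
            "sex": np.asarray(state.sex, int),
            "generation": gen_arr,
            "F": np.asarray(state.F, float),
            "tbv": np.asarray(state.tbv, float),
            "phenotype": phen,
            "ebv": ebv,
        }
    )
    retained_ids = np.sort(np.concatenate(retained)) if retained else np.array([], int)
    haps = (
        np.stack([state.haps[int(i)] for i in retained_ids])
        if len(retained_ids)
        else np.empty((0, 2, gm.n_loci), np.uint8)
    )
    a22 = 2.0 * tracker.coancestry(retained_ids, retained_ids) if len(retained_ids) else None
    meta = {
        "phase": "recent",
        "gen9": scheme.expansion_generations + scheme.selected_generations - 1,
        "gen10": scheme.expansion_generations + scheme.selected_generations,
        "A22": a22,
        "A22_ids": retained_ids,
    }
    return Population(pedigree=ped, haplotypes=haps, haplotype_ids=retained_ids, genome=gm, meta=meta)
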