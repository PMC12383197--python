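# Methods

`mbgp` simulates three cattle breeds with different linkage-disequilibrium
(LD) histories, builds mixed reference populations by genetic-distance
screening, and compares three genomic evaluation models against the
simulated truth. This note records the model, the parameter choices, the
numerical decisions, and what the simulation does and does not establish.

## Demographic model

Each replicate simulates one **ancestral trunk** population by
Wright-Fisher random mating (random union of gametes, equal sex ratio,
non-overlapping generations, no selection or migration) whose census
follows a piecewise-linear schedule. The trunk's final haplotypes seed
three **branch** populations (PopA, PopB, PopC) that then run their own
size schedules:

* **PopA** — small and stable after divergence, then expanding. Smallest
  effective size for the longest time, hence the slowest LD decay
  (highest short-range r²).
* **PopB** — declining after divergence, then recovering. Intermediate.
* **PopC** — large and stable, contracting only late. Fastest LD decay.

Founder haplotypes of the trunk are i.i.d. Bernoulli(0.5) alleles at
every locus (equal starting frequencies). Meiosis places a
Poisson(length in Morgans) number of crossovers uniformly per
chromosome, starting from a fair-coin parental haplotype; mutation is
recurrent (allele flips, no new states) at 2.5 × 10⁻⁵ per locus per
gamete.

**Why a shared trunk.** Three fully independent long histories would
leave the breeds with (a) almost no jointly polymorphic markers (drift
over t/2N ≈ 2.5 fixes >90 % of loci per population, and the joint panel
is the product across populations) and (b) independent marker–QTL
linkage phase, so records from one breed would carry no information
about another, making any mixed-reference design pointless. Real cattle
breeds diverged on the order of a hundred generations ago; the presets
therefore use a long common trunk (mutation–drift LD background) and
~100-generation breed-specific branches (full scale). Cross-breed
information transfer then exists at short range — where LD phase
persists — which is precisely the regime a mixed-reference study
investigates.

**Recent phase.** Each breed's recent history has two stages. Stage 1
(expansion): a fixed number of dam slots (e.g. 3000) each produce one
offspring per generation for 10 generations, sires drawn with
replacement from a male pool; parents are drawn from the previous
cohort. Stage 2 (selection): a breeding set of fixed size (e.g. 200
sires, 2800 dams) is maintained for 10 generations; every generation
each dam produces one offspring, EBVs are re-estimated for all animals
by pedigree BLUP on the accumulated records, and the stated replacement
fraction of sires/dams (e.g. 0.6/0.3) is culled — lowest EBV first,
older animals first on ties — and replaced by the top-EBV young males/
females of the newest cohort. Breeding founders of stage 2 are sampled
without replacement from the last two expansion cohorts pooled (a single
cohort cannot supply the stated founder counts). Genotypes and phenotype
records are retained only for the last two generations ("generation 9"
and "generation 10"); pedigree, true breeding values and inbreeding
coefficients are retained for the whole recent phase.

## Trait and phenotypes

A single additive trait: QTL effect magnitudes are gamma(shape 0.4)
draws with random signs, rescaled by one constant so that the variance
of true breeding values (TBV = Σⱼ βⱼ Q_kj, Q ∈ {0,1,2}) in the base
population — PopA's final trunk-descended historical generation —
equals σ²ₐ = 0.42. Phenotypes are y = μ + TBV + ε, ε ~ N(0, σ²ₑ = 0.58),
giving h² = 0.42 at phenotypic variance 1.0; 5 % of records are missing
at random. σ²ₑ is fixed thereafter (not re-tuned per generation), so
realized heritability drifts slightly under selection, as in standard
breeding simulators. The three breeds share the genome map and the QTL
effect vector; their QTL frequencies differ by drift, so the genetic
variance each breed expresses differs.

## Quality control

PLINK-style filters in fixed order: individuals with > 10 % missing
calls, then markers with > 10 % missing calls, minor allele frequency
< 0.05, or exact Hardy–Weinberg p < 10⁻⁵. The HWE test is the exact
conditional test (sum of the probabilities of all heterozygote counts no
more probable than the observed one, given the allele counts). Simulated
genotypes have no missing calls, so the missingness filters are
implemented but inert in the pipeline. Each breed is filtered on its
retained (generation 9–10) animals; scenario evaluation uses the
intersection of the three breeds' retained marker sets.

## Relationship matrices

* **A** (pedigree): tabular method; the sparse inverse uses Henderson's
  rules with Meuwissen–Luo inbreeding coefficients, which the simulator
  tracks exactly at birth via an incremental coancestry matrix.
* **G** (genomic): VanRaden form G = ZZ′ / Σ 2pᵢ(1−pᵢ) with Z = M − 2p
  column-centered at observed panel frequencies. With observed
  frequencies G is singular by construction (centered rows sum to
  zero), so every use conditions it: GBLUP shrinks 1 % toward a scaled
  identity; single-step blends 95 % / 5 % with A₂₂ after rescaling G's
  mean diagonal onto A₂₂'s.
* **Weighted G**: G_w = Z W Z′ / (Σ 2pᵢ(1−pᵢ) · mean w), W diagonal and
  scaled to mean 1, so W = I recovers plain G.
* **H⁻¹** (single-step): H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A₂₂⁻¹], kept in
  factored form (sparse A⁻¹ plus a dense correction block) so products
  stay cheap on multi-thousand-animal pedigrees.

## Evaluation models

All models are single-trait animal models with an intercept as the only
fixed effect and variance components fixed at the simulated truth
(λ = σ²ₑ/σ²ₐ = 0.58/0.42 ≈ 1.381); no REML step is performed, which
isolates differences between relationship structures. Henderson's mixed
model equations are solved by Jacobi-preconditioned conjugate gradients
(relative residual ≤ 10⁻⁸, max 10⁴ iterations). Models whose K is
available directly (GBLUP, wGBLUP) use the algebraically identical GLS
record-space form, which also stays defined for singular K.

**wGBLUP** is the two-pass window-weighted scheme: pass 1 estimates SNP
effects by SNP-BLUP (ridge on centered genotypes with
σ²_α = σ²ₐ / Σ 2p(1−p), which makes SNP-BLUP exactly equivalent to
GRM-GBLUP — a tested identity) on the training records only; pass 2
sets each marker's weight to the mean squared effect over the window of
2S+1 markers centered on it (clipped at the array ends, rescaled to
mean 1), rebuilds the weighted GRM and refits. One weighting iteration
only. The half-width default is S = 20; the qualitative behaviour is not
sensitive to S in the 10–50 range. "Standardized genotypes" in the SNP
model are implemented as centered (not variance-scaled) dosages so the
GBLUP equivalence is exact under the VanRaden GRM.

**Accuracy** is the Pearson correlation between GEBV and TBV over the
validation set.

## Scenarios

Genetic distances between the base breed (PopA) and each donor breed
use 1 − IBS (allele-sharing) distances on the common post-QC marker
panel, embedded by classical (Torgerson) multidimensional scaling;
donors are ranked by Euclidean distance to the PopA centroid in the
first two MDS dimensions. A scenario "A+k%B" takes all phenotyped
generation-9 PopA animals plus the k % of generation-9 PopB animals
closest to PopA ("closest" resolves the ambiguity in naming such
scenarios "top k % genetic distance"). The single-breed baseline uses
the same screened donors alone. Validation is always the donor breed's
generation 10 with phenotypes masked — the study's question is
prediction for the small breed. ssGBLUP stacks the two breeds'
pedigrees block-diagonally (no known cross-breed ancestry) and adds the
joint GRM over reference ∪ validation animals.

## Scales

Three presets share this structure and differ only in size:

| preset | genome | markers/QTL | trunk | branch | recent censuses | runtime/replicate |
|---|---|---|---|---|---|---|
| full | 29 chr, 2715.85 cM | 58,990 / 725 | 1000 gen @ 1000 | ~100 gen + 95-gen ramp | 250/3000 → 200–220/2335–2800 | hours |
| desk | 3 chr, 300 cM | 9,000 / 75 | 200 gen @ 120 | 40 gen + 19-gen ramp | ÷5 of full | ~45 s |
| micro | 2 chr, 200 cM | 800 / 40 | 60 gen @ 60 | 15 gen + 8-gen ramp | ÷10, 5+5 recent gens | ~1.5 s |

The desk preset is the routine working scale (tests, acceptance script);
micro serves repeated statistical checks. The desk marker density
(30/cM) is chosen so that, after drift losses, the jointly polymorphic
panel stays above roughly a thousand markers: the cross-breed block of G
is estimated only from shared markers, and below that density its
sampling noise (SD ~ m^−1/2 per entry) swamps the weak cross-breed
signal, reversing the benefit of mixed references. This threshold is a
property of the miniature, not of the method; at the full scale the
shared panel is tens of thousands of markers.

## What the simulation does and does not establish

The generator reproduces: the designed LD-decay ordering (PopA > PopB >
PopC at short range, checked each run), base-population h² and
phenotypic variance, Poisson recombination and binomial mutation rates,
directional selection response, and clean PCA separation of the breeds.
It does not emulate: genotyping error or missingness patterns, sex
chromosomes, overlapping generations, migration or ongoing gene flow,
dominance/epistasis, genotype-by-environment interaction, or real
linkage maps (markers are uniform on a genetic map; 1 cM is mapped to
~1 Mb for reporting). Passing tests therefore validate the estimation
machinery and the qualitative design of the study, not the field
performance of any model on real cattle data.

## Numerical and design choices

* Historical mating is random union of gametes (both parents drawn with
  replacement), matching Wright–Fisher drift expectations — the
  heterozygosity-decay test against (1 − 1/2N)ᵗ depends on this.
* Largest-remainder rounding allocates markers and QTL to chromosomes
  proportionally to map length; positions are uniform; marker and QTL
  positions are disjoint.
* Replicate means are arithmetic; per-cell results carry a status flag
  so a failed cell cannot silently drop out of a summary.
* All randomness flows from one master seed through named
  `SeedSequence` substreams (genome, trunk, per-breed histories, trait,
  per-breed recent phases), so a full experiment is a pure function of
  (configuration, seed), and stages are independently reproducible.
* Culling ties (equal EBV) resolve older-first, then by id; donor
  screening ties resolve by id.
* The MDS embedding uses only eigenpairs with positive eigenvalues and
  warns when fewer than requested exist (1 − IBS distances need not be
  Euclidean).
* Monomorphic markers inside a scenario's joint panel are excluded from
  that GRM with a warning rather than failing the cell.

## Known limitations

* ssGBLUP gains over GBLUP are small here because every reference record
  belongs to a genotyped animal; the pedigree adds links but no extra
  records. Designs with phenotyped non-genotyped animals would separate
  the two models more.
* The 15 % peak in donor fraction and the monotone decline for the
  fast-LD-decay donor — subtle interior effects reported at full scale —
  are not resolved at the reduced scales; reduced-scale runs show mixed
  references beating single-breed ones and wGBLUP leading, but the
  fraction response is noisy.
* Variance components are fixed at the simulated truth; with estimated
  components all accuracies would drop somewhat, likely without changing
  the orderings.
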