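"""Mixed-reference-population experiment: screening, scenarios, diagnostics.

The study question: can genomic prediction for a small breed be improved
by adding its closest relatives (screened by multidimensional scaling of
identity-by-state distances) to a larger breed's reference population?
Scenarios mix the base population A with the top 10/15/20% of donors from
population B or C; validation animals are the donor breed's final
generation, with phenotypes masked, and prediction accuracy is the
Pearson correlation between GEBV and true breeding value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from . import models, qc
from .presets import SimulationPreset, get_preset
from .simulate import Population, run_historical, run_recent
from .trait import draw_qtl_effects

__all__ = [
    "ScenarioSpec",
    "ExperimentConfig",
    "Replicate",
    "simulate_replicate",
    "ibs_distance_matrix",
    "classical_mds",
    "select_donors",
    "build_scenario",
    "evaluate_scenario",
    "ld_decay_curve",
    "pca_populations",
    "run_experiment",
    "accuracy_pivot",
]


# --------------------------------------------------------------------------
# replicate simulation
# --------------------------------------------------------------------------


@dataclass
class Replicate:
    genome: object
    trait: object
    populations: dict[str, Population]
    qc_reports: dict = field(default_factory=dict)
    common_markers: np.ndarray | None = None


def simulate_replicate(preset: SimulationPreset, seed) -> Replicate:
    """Simulate the three populations of one replicate.

    One genome map, one shared ancestral haplotype pool and one QTL-effect
    vector (calibrated on PopA's final historical generation) are used for
    all populations; demographic histories differ per the preset.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    names = sorted(preset.populations)
    children = ss.spawn(3 + 2 * len(names))
    genome_rng, trunk_rng, trait_rng = (np.random.default_rng(c) for c in children[:3])
    hist_rngs = {n: np.random.default_rng(c) for n, c in zip(names, children[3 : 3 + len(names)])}
    recent_rngs = {n: np.random.default_rng(c) for n, c in zip(names, children[3 + len(names) :])}

    gm = preset.build_genome(genome_rng)
    trunk = run_historical(gm, list(preset.trunk_phases), trunk_rng)
    pool = trunk.haplotypes.reshape(-1, gm.n_loci)

    historical = {
        n: run_historical(gm, list(preset.populations[n].phases), hist_rngs[n], founder_pool=pool)
        for n in names
    }
    trait = draw_qtl_effects(
        gm.n_qtl,
        preset.gamma_shape,
        preset.sigma_a2,
        historical["A"].qtl_genotypes(),
        trait_rng,
        sigma_e2=preset.sigma_e2,
    )
    pops = {
        n: run_recent(historical[n], preset.populations[n].scheme, trait, recent_rngs[n])
        for n in names
    }
    return Replicate(genome=gm, trait=trait, populations=pops)


def qc_replicate(rep: Replicate, thresholds: qc.QCThresholds = qc.QCThresholds()) -> Replicate:
    """Per-population marker QC on the retained generations; intersect kept sets."""
    kept_sets = []
    for name, pop in sorted(rep.populations.items()):
        G = pop.marker_genotypes()
        kept, _, report = qc.apply_qc_filters(G, thresholds)
        rep.qc_reports[name] = report
        kept_sets.append(set(int(k) for k in kept))
    common = sorted(set.intersection(*kept_sets))
    rep.common_markers = np.asarray(common, dtype=np.int64)
    return rep


# --------------------------------------------------------------------------
# genetic-distance screening
# --------------------------------------------------------------------------


def ibs_distance_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise 1 - IBS allele-sharing distance for a 0/1/2 genotype matrix.

    D_ab = 1 - (shared allele count)/(2m) = (sum_i |g_ai - g_bi|) / (2m).
    Computed from genotype-class indicator products so the cost is a few
    BLAS multiplies instead of an O(n^2 m) scan.
    """
    M = np.asarray(genotypes)
    if M.ndim != 2 or M.shape[1] == 0:
        raise ValueError("no shared markers")
    n, m = M.shape
    H = [np.ascontiguousarray((M == k), dtype=np.float32) for k in (0, 1, 2)]
    N = [[H[a] @ H[b].T for b in range(3)] for a in range(3)]
    absdiff = (
        N[0][1] + N[1][0] + N[1][2] + N[2][1]  # |0-1|, |1-2| classes
        + 2.0 * (N[0][2] + N[2][0])
    )
    D = absdiff / (2.0 * m)
    np.fill_diagonal(D, 0.0)
    return ((D + D.T) / 2.0).astype(float)


def classical_mds(distance_matrix: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Torgerson classical MDS of a distance matrix.

    Double-centers -D^2/2 and embeds on the top eigenpairs with positive
    eigenvalues; coordinates are ordered by eigenvalue. Requests beyond
    the positive spectrum are truncated with a warning.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    B = -0.5 * (D**2)
    B -= B.mean(axis=0)
    B -= B.mean(axis=1)[:, None]
    k = min(n_dims, n - 1)
    vals, vecs = sla.eigh(B, subset_by_index=[n - k, n - 1])
    vals, vecs = vals[::-1], vecs[:, ::-1]
    pos = vals > max(1e-12, 1e-9 * abs(vals[0])) if vals.size else np.array([], bool)
    if pos.sum() < n_dims:
        warnings.warn(
            f"only {int(pos.sum())} positive MDS eigenvalues; truncating to that many dimensions"
        )
    vals, vecs = vals[pos], vecs[:, pos]
    return vecs * np.sqrt(vals)


def select_donors(
    coords: np.ndarray,
    base_index: np.ndarray,
    donor_index: np.ndarray,
    fraction: float,
    donor_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Donors closest (Euclidean, MDS space) to the base-population centroid.

    Returns the round(fraction * n_donors) nearest donors; ties break on
    id order. ``donor_ids`` labels the donors (defaults to their indices).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    donor_index = np.asarray(donor_index)
    if donor_index.size == 0:
        raise ValueError("empty donor set")
    ids = donor_index if donor_ids is None else np.asarray(donor_ids)
    centroid = coords[np.asarray(base_index)].mean(axis=0)
    dist = np.linalg.norm(coords[donor_index] - centroid, axis=1)
    k = int(np.floor(fraction * len(donor_index) + 0.5))
    order = np.lexsort((ids, dist))
    return ids[order[:k]]


@dataclass
class DonorScreen:
    """MDS screening of one donor population against the base population."""

    ranked_ids: np.ndarray  # donor ids, nearest first
    distances: np.ndarray  # matching centroid distances
    coords: np.ndarray
    base_rows: np.ndarray
    donor_rows: np.ndarray


def screen_donors(
    base_pop: Population,
    donor_pop: Population,
    markers: np.ndarray,
    n_dims: int = 2,
) -> DonorScreen:
    base_ids = _reference_generation_ids(base_pop)
    donor_ids = _reference_generation_ids(donor_pop)
    G = np.vstack(
        [
            base_pop.marker_genotypes(base_ids)[:, markers],
            donor_pop.marker_genotypes(donor_ids)[:, markers],
        ]
    )
    D = ibs_distance_matrix(G)
    coords = classical_mds(D, n_dims)
    base_rows = np.arange(len(base_ids))
    donor_rows = np.arange(len(base_ids), len(base_ids) + len(donor_ids))
    ranked = select_donors(coords, base_rows, donor_rows, 1.0, donor_ids)
    centroid = coords[base_rows].mean(axis=0)
    dist = np.linalg.norm(coords[donor_rows] - centroid, axis=1)
    dist_by_id = dict(zip(donor_ids.tolist(), dist.tolist()))
    return DonorScreen(
        ranked_ids=ranked,
        distances=np.array([dist_by_id[int(i)] for i in ranked]),
        coords=coords,
        base_rows=base_rows,
        donor_rows=donor_rows,
    )


def _reference_generation_ids(pop: Population) -> np.ndarray:
    return pop.generation_ids(pop.meta["gen9"])


def _validation_generation_ids(pop: Population) -> np.ndarray:
    return pop.generation_ids(pop.meta["gen10"])


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    base_pop: str
    donor_pop: str
    donor_fraction: float
    mode: str  # "mixed" or "single"
    reference_def: dict  # population label -> animal ids in the reference panel
    validation_def: tuple  # (population label, animal ids)

    def __post_init__(self):
        ref_donor = set(np.asarray(self.reference_def.get(self.donor_pop, [])).tolist())
        val = set(np.asarray(self.validation_def[1]).tolist())
        if ref_donor & val:
            raise ValueError("reference and validation sets overlap")


def build_scenario(
    populations: dict[str, Population],
    donor_pop: str,
    fraction: float,
    mode: str = "mixed",
    screen: DonorScreen | None = None,
    markers: np.ndarray | None = None,
    base_pop: str = "A",
) -> ScenarioSpec:
    """Assemble one scenario's reference and validation id sets.

    Mixed mode: reference = phenotyped generation-9 base animals plus the
    screened top-``fraction`` generation-9 donors. Single-breed mode: the
    screened donors alone. Validation: all generation-10 donor-population
    animals (their phenotypes are never used).
    """
    if mode not in ("mixed", "single"):
        raise ValueError("mode must be 'mixed' or 'single'")
    base = populations[base_pop]
    donor = populations[donor_pop]
    if screen is None:
        if markers is None:
            raise ValueError("either a DonorScreen or a marker set is required")
        screen = screen_donors(base, donor, markers)
    n_donors_total = len(screen.ranked_ids)
    k = int(np.floor(fraction * n_donors_total + 0.5))
    donors = np.sort(screen.ranked_ids[:k])

    validation = _validation_generation_ids(donor)
    if validation.size == 0:
        raise ValueError("validation set is empty")
    reference = {donor_pop: donors}
    if mode == "mixed":
        ped = base.pedigree
        gen9 = _reference_generation_ids(base)
        phen = ped.set_index("id").loc[gen9, "phenotype"].to_numpy()
        reference[base_pop] = gen9[~np.isnan(phen)]
    label = f"{base_pop}+{fraction:.0%}{donor_pop}" if mode == "mixed" else f"{donor_pop}-only@{fraction:.0%}"
    return ScenarioSpec(
        name=label,
        base_pop=base_pop,
        donor_pop=donor_pop,
        donor_fraction=fraction,
        mode=mode,
        reference_def={k_: np.asarray(v) for k_, v in reference.items()},
        validation_def=(donor_pop, validation),
    )


def _panel(spec: ScenarioSpec, populations, markers):
    """Stack reference-panel genotypes/phenotypes in a fixed population order."""
    order = [p for p in sorted(populations) if p in spec.reference_def]
    blocks, ys, id_blocks = [], [], []
    for p in order:
        ids = spec.reference_def[p]
        pop = populations[p]
        blocks.append(pop.marker_genotypes(ids)[:, markers])
        ys.append(pop.pedigree.set_index("id").loc[ids, "phenotype"].to_numpy())
        id_blocks.append((p, ids))
    return order, np.vstack(blocks), np.concatenate(ys), id_blocks


def evaluate_scenario(
    spec: ScenarioSpec,
    populations: dict[str, Population],
    markers: np.ndarray,
    model: str,
    h2: float = 0.42,
    window_s: int = 20,
    blend_weight: float = 0.95,
    ridge: float = 0.01,
) -> dict:
    """Fit one model on one scenario and score validation accuracy."""
    lam = models.lambda_from_h2(h2)
    val_pop_name, val_ids = spec.validation_def
    val_pop = populations[val_pop_name]
    M_val = val_pop.marker_genotypes(val_ids)[:, markers]
    tbv_val = val_pop.pedigree.set_index("id").loc[val_ids, "tbv"].to_numpy()

    order, M_ref, y_ref, id_blocks = _panel(spec, populations, markers)

    if model == "gblup":
        res = models.run_gblup(M_ref, M_val, y_ref, lam=lam, ridge=ridge)
        gebv_val = res.gebv[len(M_ref) :]
    elif model == "wgblup":
        res = models.run_wgblup(M_ref, M_val, y_ref, S=window_s, lam=lam, h2=h2, ridge=ridge)
        gebv_val = res.gebv[len(M_ref) :]
    elif model == "ssgblup":
        gebv_val = _ssgblup_scenario(spec, populations, markers, id_blocks, val_ids, lam, blend_weight)
    else:
        raise ValueError(f"unknown model {model!r}")

    acc = models.accuracy(gebv_val, tbv_val)
    return {
        "accuracy": acc,
        "n_reference": int(np.sum(~np.isnan(y_ref))),
        "n_panel": len(M_ref),
        "n_validation": len(val_ids),
    }


def _ssgblup_scenario(spec, populations, markers, id_blocks, val_ids, lam, blend_weight):
    """Single-step evaluation: stacked per-breed pedigrees, joint GRM."""
    val_pop_name = spec.validation_def[0]
    pop_names = [p for p, _ in id_blocks]
    if val_pop_name not in pop_names:
        pop_names.append(val_pop_name)

    offsets, sires, dams, Fs, n_total = {}, [], [], [], 0
    for p in pop_names:
        ped = populations[p].pedigree
        offsets[p] = n_total
        s = ped["sire"].to_numpy()
        d = ped["dam"].to_numpy()
        sires.append(np.where(s > 0, s - 1 + n_total, -1))
        dams.append(np.where(d > 0, d - 1 + n_total, -1))
        Fs.append(ped["F"].to_numpy())
        n_total += len(ped)
    sire = np.concatenate(sires)
    dam = np.concatenate(dams)
    F = np.concatenate(Fs)

    # genotyped block: panel animals per population, validation appended to
    # its own population's segment so A22 stays block-diagonal by breed
    geno_ids_by_pop: dict[str, np.ndarray] = {}
    for p, ids in id_blocks:
        geno_ids_by_pop[p] = np.asarray(ids)
    geno_ids_by_pop[val_pop_name] = np.unique(
        np.concatenate([geno_ids_by_pop.get(val_pop_name, np.array([], int)), val_ids])
    )

    geno_rows, M_blocks, a22_blocks = [], [], []
    for p in pop_names:
        ids = geno_ids_by_pop.get(p)
        if ids is None or len(ids) == 0:
            continue
        pop = populations[p]
        geno_rows.append(ids - 1 + offsets[p])
        M_blocks.append(pop.marker_genotypes(ids)[:, markers])
        a22_ids = pop.meta["A22_ids"]
        pos = np.searchsorted(a22_ids, ids)
        a22_blocks.append(pop.meta["A22"][np.ix_(pos, pos)])
    genotyped_index = np.concatenate(geno_rows)
    M = np.vstack(M_blocks)
    A22 = sla.block_diag(*a22_blocks)

    # records: phenotyped reference-panel animals
    rec_rows, rec_y = [], []
    for p, ids in id_blocks:
        ped = populations[p].pedigree.set_index("id")
        y = ped.loc[ids, "phenotype"].to_numpy()
        keep = ~np.isnan(y)
        rec_rows.append(np.asarray(ids)[keep] - 1 + offsets[p])
        rec_y.append(y[keep])
    record_rows = np.concatenate(rec_rows)
    y = np.concatenate(rec_y)

    p_freq = M.mean(axis=0) / 2.0
    keep = (p_freq > 0.0) & (p_freq < 1.0)
    from .kinship import genomic_relationship

    G = genomic_relationship(M[:, keep], p_freq[keep])
    res = models.run_ssgblup(
        sire,
        dam,
        record_rows,
        y,
        genotyped_index,
        genotypes=None,
        lam=lam,
        blend_weight=blend_weight,
        F=F,
        A22=A22,
        G=G,
    )
    val_global = val_ids - 1 + offsets[val_pop_name]
    return res.gebv[val_global]


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------


def ld_decay_curve(
    genotypes: np.ndarray,
    chrom: np.ndarray,
    pos_cM: np.ndarray,
    bins_cM: np.ndarray | None = None,
    max_pairs: int = 50_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean r^2 between intra-chromosome marker pairs, binned by distance.

    Distances are genetic (cM); at the study's marker density 1 cM maps to
    roughly 1 Mb. Bins with no sampled pairs are omitted from the output.
    """
    if bins_cM is None:
        bins_cM = np.linspace(0.0, 1.0, 11)
    rng = np.random.default_rng(0) if rng is None else rng
    Z = np.asarray(genotypes, dtype=float)
    Z = Z - Z.mean(axis=0)
    norms = np.sqrt((Z**2).sum(axis=0))
    max_d = float(bins_cM[-1])

    pairs_i, pairs_j = [], []
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos_cM[idx]
        # neighbours within max_d of each marker (positions are sorted)
        hi = np.searchsorted(p, p + max_d, side="right")
        counts = hi - np.arange(len(idx)) - 1
        total = counts.sum()
        if total == 0:
            continue
        starts = np.concatenate([[0], np.cumsum(counts)])
        flat = rng.choice(total, size=min(max_pairs, total), replace=False) if total > max_pairs else np.arange(total)
        left = np.searchsorted(starts, flat, side="right") - 1
        offset = flat - starts[left] + 1
        pairs_i.append(idx[left])
        pairs_j.append(idx[left + offset])
    if not pairs_i:
        raise ValueError("no intra-chromosome marker pairs within the bin range")
    i = np.concatenate(pairs_i)
    j = np.concatenate(pairs_j)
    ok = (norms[i] > 0) & (norms[j] > 0)
    i, j = i[ok], j[ok]
    r = np.einsum("ni,ni->i", Z[:, i], Z[:, j]) / (norms[i] * norms[j])
    d = np.abs(pos_cM[j] - pos_cM[i])

    which = np.digitize(d, bins_cM) - 1
    rows = []
    for b in range(len(bins_cM) - 1):
        mask = which == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin_low_cM": bins_cM[b],
                "bin_high_cM": bins_cM[b + 1],
                "mean_r2": float(np.mean(r[mask] ** 2)),
                "n_pairs": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def pca_populations(genotypes: np.ndarray, n_components: int = 2):
    """PCA of centered genotypes; returns projections and variance fractions."""
    Z = np.asarray(genotypes, dtype=float)
    n = Z.shape[0]
    if n_components > n:
        raise ValueError("more components requested than animals")
    Z = Z - Z.mean(axis=0)
    C = Z @ Z.T
    total = np.trace(C)
    k = min(n_components, n - 1)
    vals, vecs = sla.eigh(C, subset_by_index=[n - k, n - 1])
    vals, vecs = np.maximum(vals[::-1], 0.0), vecs[:, ::-1]
    coords = vecs * np.sqrt(vals)
    fractions = vals / total if total > 0 else np.zeros_like(vals)
    return coords, fractions


# --------------------------------------------------------------------------
# the experiment
# --------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    preset: str | SimulationPreset = "desk"
    fractions: tuple[float, ...] = (0.10, 0.15, 0.20)
    models: tuple[str, ...] = ("gblup", "ssgblup", "wgblup")
    modes: tuple[str, ...] = ("mixed", "single")
    donor_pops: tuple[str, ...] = ("B", "C")
    base_pop: str = "A"
    window_s: int = 20
    blend_weight: float = 0.95
    ridge: float = 0.01
    mds_dims: int = 2
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    diagnostics: bool = False

    def resolve_preset(self) -> SimulationPreset:
        return self.preset if isinstance(self.preset, SimulationPreset) else get_preset(self.preset)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "qc_thresholds" in d and isinstance(d["qc_thresholds"], dict):
            d["qc_thresholds"] = qc.QCThresholds(**d["qc_thresholds"])
        for key in ("fractions", "models", "modes", "donor_pops"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def run_replicate(config: ExperimentConfig, seed, replicate_index: int = 0):
    """Simulate, QC, screen and evaluate all cells of one replicate."""
    preset = config.resolve_preset()
    rep = simulate_replicate(preset, seed)
    qc_replicate(rep, config.qc_thresholds)
    markers = rep.common_markers
    pops = rep.populations

    screens = {
        d: screen_donors(pops[config.base_pop], pops[d], markers, config.mds_dims)
        for d in config.donor_pops
    }
    rows = []
    for donor in config.donor_pops:
        for fraction in config.fractions:
            for mode in config.modes:
                spec = build_scenario(
                    pops, donor, fraction, mode, screen=screens[donor], base_pop=config.base_pop
                )
                for model in config.models:
                    row = {
                        "replicate": replicate_index,
                        "scenario": spec.name,
                        "mode": mode,
                        "donor_pop": donor,
                        "fraction": fraction,
                        "model": model,
                        "status": "ok",
                        "accuracy": np.nan,
                        "n_reference": np.nan,
                        "n_validation": np.nan,
                    }
                    try:
                        out = evaluate_scenario(
                            spec,
                            pops,
                            markers,
                            model,
                            h2=preset.h2,
                            window_s=config.window_s,
                            blend_weight=config.blend_weight,
                            ridge=config.ridge,
                        )
                        row.update(
                            accuracy=out["accuracy"],
                            n_reference=out["n_reference"],
                            n_validation=out["n_validation"],
                        )
                    except Exception as exc:  # record the failure, keep going
                        row["status"] = f"failed: {exc}"
                    rows.append(row)
    return pd.DataFrame(rows), rep, screens


def run_experiment(
    config: ExperimentConfig, n_replicates: int, master_seed: int
) -> tuple[pd.DataFrame, dict]:
    """Full experiment: replicates x scenarios x models.

    Returns the long-format result table and a diagnostics dict (QC
    reports always; LD/PCA/MDS summaries from the first replicate when
    ``config.diagnostics`` is set).
    """
    ss = np.random.SeedSequence(master_seed)
    rep_seeds = ss.spawn(n_replicates)
    tables, diagnostics = [], {"qc": {}}
    for r in range(n_replicates):
        table, rep, screens = run_replicate(config, rep_seeds[r], replicate_index=r)
        tables.append(table)
        diagnostics["qc"][r] = {k: v.to_dict() for k, v in rep.qc_reports.items()}
        if config.diagnostics and r == 0:
            diagnostics.update(_first_replicate_diagnostics(config, rep, screens))
    return pd.concat(tables, ignore_index=True), diagnostics


def _first_replicate_diagnostics(config, rep, screens) -> dict:
    markers = rep.common_markers
    gm = rep.genome
    mchrom = gm.locus_chrom[gm.marker_index][markers]
    mpos = gm.locus_pos_cM[gm.marker_index][markers]
    ld, pca_blocks, labels = {}, [], []
    for name, pop in sorted(rep.populations.items()):
        ids = _validation_generation_ids(pop)
        G = pop.marker_genotypes(ids)[:, markers]
        ld[name] = ld_decay_curve(G, mchrom, mpos)
        pca_blocks.append(G)
        labels.extend([name] * len(G))
    coords, fracs = pca_populations(np.vstack(pca_blocks), 2)
    mds_distance = {
        d: {
            f: float(np.mean(s.distances[: int(np.floor(f * len(s.ranked_ids) + 0.5))]))
            for f in config.fractions
        }
        for d, s in screens.items()
    }
    return {
        "ld_decay": ld,
        "pca": {"coords": coords, "variance_fractions": fracs, "labels": np.asarray(labels)},
        "mds_distance": mds_distance,
    }


def accuracy_pivot(results: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean accuracy in the published table layout.

    Rows: mixing fraction; columns: (model, donor population); mixed-mode
    scenarios only.
    """
    mixed = results[(results["mode"] == "mixed") & (results["status"] == "ok")]
    return mixed.pivot_table(
        index="fraction", columns=["model", "donor_pop"], values="accuracy", aggfunc="mean"
    )
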