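"""Synthetic Charolais x Holstein F2 cross with planted cis/trans eQTL.

The generator reproduces the statistical structure the pipeline assumes: a
three-generation pedigree (five purebred sires mated to purebred dams of a
second breed; five F2 full/half-sib families of sizes 49, 35, 52, 8 and 1
by default, 145 cows in all), SNP genotypes dropped through that pedigree
with Haldane recombination (so the F2 carries the long-range linkage
disequilibrium characteristic of a two-breed cross), year-season and age
fixed effects, a polygenic component with covariance sigma2_a * A over the
parent generations, planted per-allele eQTL effects, and residuals from
configurable non-normal families (right-skewed shifted-lognormal, heavy-
tailed Student t3, short-tailed uniform) standardized so the residual
variance is exactly sigma2_e. A truth table records every planted effect
and the per-transcript nuisance parameters for parameter-recovery tests.

Everything is driven by one integer seed; fixing it fixes every output
byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CovariateTable, ExpressionMatrix, GeneMap, GenotypeMatrix, SnpMap
from .pedigree import (
    PedigreeTable,
    RelationshipMatrix,
    build_relationship_matrix,
    validate_pedigree,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "generate_pedigree",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_dataset",
    "write_dataset",
]

RESIDUAL_FAMILIES = ("normal", "lognormal_shifted", "student_t", "uniform")
_BP_PER_MORGAN = 100_000_000  # ~1 cM per Mb


@dataclass
class SimulationConfig:
    """Study-shaped defaults; all knobs overridable.

    ``family_sizes`` are the F2 cow counts of the five full/half-sib
    families; ``founder_freq_divergence`` in [0, 1] pulls the two founder
    breeds' allele frequencies apart (1 = fixed for alternate alleles).
    ``effect_size_sd`` is the per-allele additive effect magnitude of a
    planted eQTL in expression (log2) units; signs are random.
    ``residual_family`` is one of the four named families or "mixed"
    (cycled across transcripts and recorded in the truth table).
    """

    n_sires: int = 5
    family_sizes: tuple[int, ...] = (49, 35, 52, 8, 1)
    n_p0_dams: int = 33
    f2_per_f1_dam: int = 4
    n_chromosomes: int = 5
    snps_per_chromosome: int = 40
    chromosome_length_morgans: float = 1.0
    founder_freq_divergence: float = 0.6
    n_transcripts: int = 100
    n_cis_eqtl: int = 10
    n_trans_eqtl: int = 5
    effect_size_sd: float = 1.0
    sigma2_a: float = 0.25
    sigma2_e: float = 0.75
    season_effect_sd: float = 0.5
    residual_family: str = "mixed"
    n_seasons: int = 25
    age_beta: float = 0.002
    age_range_days: tuple[float, float] = (1300.0, 1500.0)
    seed: int = 0

    def __post_init__(self):
        if len(self.family_sizes) != self.n_sires:
            raise ValueError("family_sizes length must equal n_sires")
        if any(s < 0 for s in self.family_sizes):
            raise ValueError("family sizes must be >= 0")
        if not 0 <= self.founder_freq_divergence <= 1:
            raise ValueError("founder_freq_divergence must be in [0, 1]")
        if self.sigma2_a < 0 or self.sigma2_e < 0:
            raise ValueError("variances must be >= 0")
        if self.residual_family not in RESIDUAL_FAMILIES + ("mixed",):
            raise ValueError(f"unknown residual_family {self.residual_family!r}")


@dataclass
class TruthTable:
    """Ground truth: planted eQTL and per-transcript nuisance parameters."""

    eqtl: pd.DataFrame  # snp_id, transcript_id, effect_per_allele, class
    transcripts: pd.DataFrame  # transcript_id, sigma2_a, sigma2_e, beta_age,
    #                            residual_family
    season_effects: pd.DataFrame  # transcript_id, season_class, effect


def generate_pedigree(cfg: SimulationConfig) -> PedigreeTable:
    """Three-generation MOET-style pedigree with the study's family sizes.

    Family i descends from purebred sire CHA_i through one F1 bull; the F1
    dams of family i are daughters of sire i+1 (mod n), so within-family
    matings are between unrelated F1 animals. F2 cows are assigned to F1
    dams in blocks of ``f2_per_f1_dam`` (full-sib groups within the
    paternal half-sib family). The P0 dam pool is recycled across F1s.
    """
    rows = []
    sires = [f"CHA_{i+1}" for i in range(cfg.n_sires)]
    dams = [f"HOL_{i+1}" for i in range(cfg.n_p0_dams)]
    for s in sires:
        rows.append((s, None, None, "P0"))
    for d in dams:
        rows.append((d, None, None, "P0"))

    dam_cycle = 0

    def next_p0_dam() -> str:
        nonlocal dam_cycle
        d = dams[dam_cycle % len(dams)]
        dam_cycle += 1
        return d

    f2_counter = 0
    for fam, size in enumerate(cfg.family_sizes):
        f1_sire = f"F1S_{fam+1}"
        rows.append((f1_sire, sires[fam], next_p0_dam(), "F1"))
        n_dams = max(1, math.ceil(size / cfg.f2_per_f1_dam))
        maternal_sire = sires[(fam + 1) % cfg.n_sires]
        f1_dams = []
        for k in range(n_dams):
            f1_dam = f"F1D_{fam+1}_{k+1}"
            rows.append((f1_dam, maternal_sire, next_p0_dam(), "F1"))
            f1_dams.append(f1_dam)
        for j in range(size):
            f2_counter += 1
            rows.append(
                (
                    f"F2_{f2_counter:03d}",
                    f1_sire,
                    f1_dams[j // cfg.f2_per_f1_dam % n_dams],
                    "F2",
                )
            )
    return validate_pedigree(rows)


def _snp_layout(cfg: SimulationConfig):
    """Deterministic SNP ids, chromosome labels and bp positions."""
    ids, chroms, pos = [], [], []
    L = cfg.chromosome_length_morgans
    m = cfg.snps_per_chromosome
    for c in range(cfg.n_chromosomes):
        pos_morgan = np.linspace(0.0, L, m) if m > 1 else np.array([L / 2])
        for k in range(m):
            ids.append(f"snp_c{c+1}_{k+1:04d}")
            chroms.append(c + 1)
            pos.append(1 + int(round(pos_morgan[k] * _BP_PER_MORGAN)))
    return ids, np.array(chroms), np.array(pos)


def _founder_breed(ped: PedigreeTable) -> dict[str, str]:
    """Founders used as sires are breed A (Charolais), as dams breed B."""
    as_sire = set(ped.df["sire"].dropna())
    breeds = {}
    for f in ped.founders:
        breeds[f] = "A" if f in as_sire else "B"
    return breeds


def _meiosis(
    haplo: np.ndarray, rec: np.ndarray, chrom_slices, rng
) -> np.ndarray:
    """One gamete from a diploid (2 x n_snps) under Haldane recombination.

    Along each chromosome the source haplotype follows a Markov chain that
    switches between adjacent markers with the map-distance recombination
    fraction r = (1 - exp(-2d)) / 2 — exact for a no-interference model.
    """
    n_snps = haplo.shape[1]
    gamete = np.empty(n_snps, dtype=np.int8)
    for sl, r in zip(chrom_slices, rec):
        m = sl.stop - sl.start
        switches = rng.random(m - 1) < r if m > 1 else np.empty(0, dtype=bool)
        start = int(rng.integers(2))
        cum = np.concatenate([[0], np.cumsum(switches)])
        state = (start + cum) % 2
        gamete[sl] = haplo[state, np.arange(sl.start, sl.stop)]
    return gamete


def simulate_genotypes(
    ped: PedigreeTable, cfg: SimulationConfig
) -> tuple[GenotypeMatrix, SnpMap]:
    """Drop founder haplotypes through the pedigree (Haldane map function).

    Founder allele frequencies per breed: a Beta(2, 2) base frequency p0
    per SNP, pulled toward 1 for breed A and 0 for breed B by the
    divergence d: p_A = (1-d) p0 + d, p_B = (1-d) p0. SNPs are evenly
    spaced; bp positions use 1 cM ~ 1 Mb.
    """
    rng = np.random.default_rng(cfg.seed)
    n_chrom = cfg.n_chromosomes
    m = cfg.snps_per_chromosome
    L = cfg.chromosome_length_morgans
    n_snps = n_chrom * m

    snp_ids, chrom_arr, pos_arr = _snp_layout(cfg)
    map_rows = [
        (s, str(c), int(p)) for s, c, p in zip(snp_ids, chrom_arr, pos_arr)
    ]
    chrom_slices = []
    rec = []
    for c in range(n_chrom):
        pos_morgan = np.linspace(0.0, L, m) if m > 1 else np.array([L / 2])
        start = c * m
        chrom_slices.append(slice(start, start + m))
        d = np.diff(pos_morgan)
        rec.append((1.0 - np.exp(-2.0 * d)) / 2.0)

    p0 = rng.beta(2.0, 2.0, size=n_snps)
    d = cfg.founder_freq_divergence
    freq = {"A": (1 - d) * p0 + d, "B": (1 - d) * p0}

    breeds = _founder_breed(ped)
    index = {a: i for i, a in enumerate(ped.animals)}
    sire = [index.get(s) if s is not None else None for s in ped.df["sire"]]
    dam = [index.get(x) if x is not None else None for x in ped.df["dam"]]
    n_animals = len(ped)
    haplos = np.empty((n_animals, 2, n_snps), dtype=np.int8)
    for i, animal in enumerate(ped.animals):
        if sire[i] is None and dam[i] is None:
            p = freq[breeds[animal]]
            haplos[i] = (rng.random((2, n_snps)) < p).astype(np.int8)
        else:
            # both parents known by construction for non-founders here
            haplos[i, 0] = _meiosis(haplos[sire[i]], rec, chrom_slices, rng)
            haplos[i, 1] = _meiosis(haplos[dam[i]], rec, chrom_slices, rng)
    dosage = haplos.sum(axis=1).astype(float)
    G = GenotypeMatrix(ped.animals, snp_ids, dosage)
    snp_map = SnpMap(
        pd.DataFrame(map_rows, columns=["snp_id", "chromosome", "position_bp"])
    )
    return G, snp_map


def _standardized_residuals(rng, family: str, size) -> np.ndarray:
    """Zero-mean unit-variance draws from the named shape family."""
    if family == "normal":
        return rng.standard_normal(size)
    if family == "lognormal_shifted":
        # lognormal(0, 1): mean e^{1/2}, var (e - 1) e
        x = rng.lognormal(0.0, 1.0, size)
        return (x - math.exp(0.5)) / math.sqrt((math.e - 1.0) * math.e)
    if family == "student_t":
        return rng.standard_t(3, size) / math.sqrt(3.0)
    if family == "uniform":
        return rng.uniform(-math.sqrt(3.0), math.sqrt(3.0), size)
    raise ValueError(f"unknown residual family {family!r}")


def _psd_factor(A: np.ndarray) -> np.ndarray:
    d, U = np.linalg.eigh((A + A.T) / 2.0)
    return U * np.sqrt(np.clip(d, 0.0, None))


def simulate_expression(
    G: GenotypeMatrix,
    ped: PedigreeTable,
    A: RelationshipMatrix,
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, CovariateTable, GeneMap, TruthTable]:
    """Generate F2 expression under the sire-dam model, generatively.

    Per transcript: season effects + age slope + half the sum of the
    parents' additive effects (drawn with covariance sigma2_a * A over the
    parent generations) + planted eQTL effects (effect_per_allele x dosage)
    + standardized residuals scaled to sigma2_e. Genes are placed uniformly
    on the simulated chromosomes; a planted cis eQTL uses the SNP nearest
    its gene's start, a trans eQTL a SNP from a different chromosome.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 7]).generate_state(1)[0]
    )
    f2 = [a for a, g in zip(ped.animals, ped.df["generation"]) if g == "F2"]
    if not f2:
        raise ValueError("pedigree has no F2 animals")
    n = len(f2)
    Gf2 = G.subset(samples=f2)

    # gene placement
    chrom_len_bp = int(round(cfg.chromosome_length_morgans * _BP_PER_MORGAN))
    tids = [f"tx_{t+1:04d}" for t in range(cfg.n_transcripts)]
    gene_chrom = rng.integers(1, cfg.n_chromosomes + 1, size=cfg.n_transcripts)
    gene_start = rng.integers(1, max(chrom_len_bp, 2), size=cfg.n_transcripts)
    gene_map = GeneMap(
        pd.DataFrame(
            {
                "transcript_id": tids,
                "gene_id": [f"gene_{t+1:04d}" for t in range(cfg.n_transcripts)],
                "chromosome": [str(c) for c in gene_chrom],
                "start_bp": gene_start,
            }
        )
    )

    # planted eQTL
    n_planted = cfg.n_cis_eqtl + cfg.n_trans_eqtl
    if n_planted > 0 and Gf2.n_snps == 0:
        raise ValueError("planted eQTL requested but no SNPs available")
    if n_planted > cfg.n_transcripts:
        raise ValueError("more planted eQTL than transcripts")
    eqtl_rows = []
    target_tx = rng.choice(cfg.n_transcripts, size=n_planted, replace=False)
    _, snp_chrom_arr, snp_pos_arr = _snp_layout(cfg)
    for idx, t in enumerate(target_tx):
        is_cis = idx < cfg.n_cis_eqtl
        gc, gs = int(gene_chrom[t]), int(gene_start[t])
        if is_cis:
            candidates = np.nonzero(snp_chrom_arr == gc)[0]
        else:
            candidates = np.nonzero(snp_chrom_arr != gc)[0]
        if len(candidates) == 0:
            raise ValueError("no SNP available for requested eQTL class")
        if is_cis:
            snp_idx = candidates[np.argmin(np.abs(snp_pos_arr[candidates] - gs))]
        else:
            snp_idx = int(rng.choice(candidates))
        effect = cfg.effect_size_sd * (1.0 if rng.random() < 0.5 else -1.0)
        eqtl_rows.append(
            {
                "snp_id": G.snp_ids[snp_idx],
                "transcript_id": tids[t],
                "effect_per_allele": effect,
                "class": "cis" if is_cis else "trans",
                "snp_index": int(snp_idx),
            }
        )

    # covariates: seasons cyclic, ages uniform
    seasons = [f"S{(i % cfg.n_seasons) + 1:02d}" for i in range(n)]
    ages = rng.uniform(*cfg.age_range_days, size=n)
    cov = CovariateTable(
        pd.DataFrame(
            {"sample_id": f2, "season_class": seasons, "age_days": ages}
        )
    )

    # parent incidence for the generative polygenic term
    ped_lookup = {r.animal: (r.sire, r.dam) for r in ped.df.itertuples()}
    parent_set = sorted(
        {p for a in f2 for p in ped_lookup[a]}, key=ped.animals.index
    )
    A_par = A.subset(parent_set)
    Lfac = _psd_factor(A_par.A) * math.sqrt(cfg.sigma2_a)
    parent_pos = {p: i for i, p in enumerate(parent_set)}
    sire_idx = np.array([parent_pos[ped_lookup[a][0]] for a in f2])
    dam_idx = np.array([parent_pos[ped_lookup[a][1]] for a in f2])

    season_levels = sorted(set(seasons))
    season_code = np.array([season_levels.index(s) for s in seasons])

    families = (
        [cfg.residual_family] * cfg.n_transcripts
        if cfg.residual_family != "mixed"
        else [RESIDUAL_FAMILIES[t % 4] for t in range(cfg.n_transcripts)]
    )

    values = np.empty((n, cfg.n_transcripts))
    season_rows = []
    tx_rows = []
    planted_by_tx = {row["transcript_id"]: row for row in eqtl_rows}
    for t, tid in enumerate(tids):
        s_eff = rng.normal(0.0, cfg.season_effect_sd, size=len(season_levels))
        a = Lfac @ rng.standard_normal(len(parent_set))
        eps = _standardized_residuals(rng, families[t], n) * math.sqrt(
            cfg.sigma2_e
        )
        y = (
            s_eff[season_code]
            + cfg.age_beta * ages
            + 0.5 * (a[sire_idx] + a[dam_idx])
            + eps
        )
        if tid in planted_by_tx:
            row = planted_by_tx[tid]
            y = y + row["effect_per_allele"] * Gf2.dosage[:, row["snp_index"]]
        values[:, t] = y
        tx_rows.append(
            {
                "transcript_id": tid,
                "sigma2_a": cfg.sigma2_a,
                "sigma2_e": cfg.sigma2_e,
                "beta_age": cfg.age_beta,
                "residual_family": families[t],
            }
        )
        for lvl, e in zip(season_levels, s_eff):
            season_rows.append(
                {"transcript_id": tid, "season_class": lvl, "effect": float(e)}
            )

    truth = TruthTable(
        eqtl=pd.DataFrame(
            eqtl_rows,
            columns=["snp_id", "transcript_id", "effect_per_allele", "class", "snp_index"],
        ).drop(columns=["snp_index"]),
        transcripts=pd.DataFrame(tx_rows),
        season_effects=pd.DataFrame(season_rows),
    )
    E = ExpressionMatrix(f2, tids, values)
    return E, cov, gene_map, truth


def simulate_dataset(cfg: SimulationConfig):
    """Full pipeline input bundle: pedigree, A, genotypes, maps, expression.

    Returns a dict with keys ``pedigree``, ``A``, ``genotypes`` (all
    animals), ``genotypes_f2``, ``snp_map``, ``expression``, ``covariates``,
    ``gene_map``, ``truth``.
    """
    ped = generate_pedigree(cfg)
    A = build_relationship_matrix(ped)
    G, snp_map = simulate_genotypes(ped, cfg)
    E, cov, gene_map, truth = simulate_expression(G, ped, A, cfg)
    f2 = E.sample_ids
    return {
        "pedigree": ped,
        "A": A,
        "genotypes": G,
        "genotypes_f2": G.subset(samples=f2),
        "snp_map": snp_map,
        "expression": E,
        "covariates": cov,
        "gene_map": gene_map,
        "truth": truth,
    }


def write_dataset(bundle: dict, out_dir, genotype_format: str = "plink_text") -> None:
    """Write a simulated bundle in the formats the pipeline reads."""
    from . import io as rio
    from .pedigree import write_pedigree_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if genotype_format == "plink_text":
        rio.write_plink_text(
            bundle["genotypes_f2"], bundle["snp_map"], out / "genotypes"
        )
    elif genotype_format == "vcf":
        rio.write_vcf(
            bundle["genotypes_f2"], bundle["snp_map"], out / "genotypes.vcf"
        )
    else:
        raise ValueError(f"unknown genotype format {genotype_format!r}")
    rio.write_expression_tsv(bundle["expression"], out / "expression.tsv")
    rio.write_covariates_csv(bundle["covariates"], out / "covariates.csv")
    write_pedigree_csv(bundle["pedigree"], out / "pedigree.csv")
    rio.write_snp_map_tsv(bundle["snp_map"], out / "snp_map.tsv")
    rio.write_gene_map_tsv(bundle["gene_map"], out / "gene_map.tsv")
    truth: TruthTable = bundle["truth"]
    truth.eqtl.to_csv(out / "truth.tsv", sep="\t", index=False)
    truth.transcripts.to_csv(out / "truth_transcripts.tsv", sep="\t", index=False)
    truth.season_effects.to_csv(out / "truth_seasons.tsv", sep="\t", index=False)
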