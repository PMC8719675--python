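"""Two-cohort case-control simulator with haploblock LD and G×E effects.

The generator emulates the structure of a two-site European candidate-SNP
study: two populations of fixed size, SNPs organised in haploblocks (one of
them very large, mimicking an extended intergenic LD block such as 1p31.1),
mild allele-frequency divergence between the sites, and a binary migraine
outcome produced by a logistic liability over age, sex, site, lifetime
depression, SNP main effects and SNP×depression interaction effects.

Haplotypes are generated from a latent AR(1) Gaussian per block, thresholded
at each SNP's allele-frequency quantile; two haplotypes are summed into a
hard-call dosage.  Population allele frequencies follow a Balding–Nichols
model around the ancestral MAF.  Lifetime depression is simulated
independently of genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from gxemig.genio import GenotypeMatrix, validate_phenotypes, write_ped_map, write_phenotypes

POP_LABELS = ("BUD", "MAN")


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation settings."""


@dataclass(frozen=True)
class BlockSpec:
    """One haploblock: a run of SNPs with AR(1) latent LD.

    ``ld_decay`` is the adjacent-SNP latent correlation: 0 gives independent
    SNPs, 1 makes every SNP in the block a copy of the same latent draw.
    """

    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.0
    chromosome: str = "1"
    start_pos: int = 1_000_000
    spacing: int = 5_000

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("block needs n_snps >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range {self.maf_range} not within (0, 0.5]")
        if not (0.0 <= self.ld_decay <= 1.0):
            raise ConfigurationError("ld_decay must be in [0, 1]")


@dataclass(frozen=True)
class EffectSpec:
    """Per-SNP liability contribution.

    ``beta_main`` is the log-odds per effect allele in everyone;
    ``beta_interaction`` is the additional log-odds per effect allele in
    individuals with lifetime depression.
    """

    snp_id: str
    beta_main: float = 0.0
    beta_interaction: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta_main) and np.isfinite(self.beta_interaction)):
            raise ConfigurationError("effect sizes must be finite")


@dataclass(frozen=True)
class CohortConfig:
    """Study-level settings for the two simulated sites.

    Defaults mirror the target study scale: 839 + 976 individuals, ~30%
    lifetime-depression prevalence, a strong depression→migraine effect and
    weak demographic effects, with mild between-site allele-frequency
    divergence.
    """

    n_per_population: tuple[int, int] = (839, 976)
    depression_prevalence: tuple[float, float] = (0.3, 0.3)
    intercept: float = -1.4
    beta_age: float = 0.1          # per SD of age
    beta_sex: float = float(np.log(1.5))   # female (SEX==2) vs male
    beta_pop: float = 0.1          # second site vs first
    beta_depression: float = float(np.log(3.0))
    stratification_divergence: float = 0.01
    missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_population):
            raise ConfigurationError("population sizes must be positive")
        prev = self.depression_prevalence
        if isinstance(prev, (int, float)):
            object.__setattr__(self, "depression_prevalence", (float(prev), float(prev)))
            prev = self.depression_prevalence
        if any(not 0.0 <= p <= 1.0 for p in prev):
            raise ConfigurationError("depression prevalence must be in [0, 1]")
        if not 0.0 <= self.stratification_divergence <= 0.2:
            raise ConfigurationError("stratification_divergence must be in [0, 0.2]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")


def default_blocks() -> list[BlockSpec]:
    """Desk-scale block layout: one very large haploblock plus smaller
    blocks and an unlinked background, ~1000 SNPs in total.

    The background has to be reasonably large: the method-of-moments
    relatedness estimate used in QC has sampling noise ~1/sqrt(m) over m
    pruned SNPs, so a few hundred independent SNPs are needed before the
    π̂ ≤ 0.1875 threshold stops flagging unrelated pairs by chance.
    """
    return [
        BlockSpec(120, (0.05, 0.45), ld_decay=0.9, chromosome="1",
                  start_pos=68_000_000, spacing=10_000),   # large 1p31.1-like block
        BlockSpec(60, (0.05, 0.45), ld_decay=0.8, chromosome="1",
                  start_pos=81_000_000, spacing=8_000),    # gene-sized block
        BlockSpec(15, (0.05, 0.45), ld_decay=0.7, chromosome="4",
                  start_pos=57_000_000, spacing=6_000),
        BlockSpec(15, (0.05, 0.45), ld_decay=0.7, chromosome="10",
                  start_pos=100_000_000, spacing=6_000),
        BlockSpec(800, (0.05, 0.45), ld_decay=0.0, chromosome="2",
                  start_pos=10_000_000, spacing=50_000),   # unlinked background
    ]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _block_haplotypes(
    rng: np.random.Generator, n_hap: int, freqs: np.ndarray, ld_decay: float
) -> np.ndarray:
    """AR(1) latent Gaussian haplotypes thresholded at allele-freq quantiles."""
    m = len(freqs)
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1))
        rho = ld_decay
        scale = np.sqrt(max(1.0 - rho * rho, 0.0))
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * innov[:, j - 1]
    thresholds = ndtri(np.clip(freqs, 1e-12, 1 - 1e-12))
    return (z < thresholds).astype(np.int8)


def simulate_genotypes(
    blocks: Sequence[BlockSpec], config: CohortConfig
) -> GenotypeMatrix:
    """Simulate hard-call dosages for both populations.

    Per-population allele frequencies are drawn Balding–Nichols style:
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the ancestral frequency ``p``
    with ``F = stratification_divergence`` (``F = 0`` leaves frequencies
    identical across populations).  Dosages count the allele whose ancestral
    frequency is the MAF.
    """
    if not blocks:
        raise ConfigurationError("need at least one block")
    rng = np.random.default_rng(config.seed)
    n_bud, n_man = config.n_per_population
    n_total = n_bud + n_man
    F = config.stratification_divergence

    dosage_cols: list[np.ndarray] = []
    meta_rows: list[tuple] = []
    counter = 0
    for b, block in enumerate(blocks):
        ancestral = rng.uniform(*block.maf_range, size=block.n_snps)
        pop_freqs = []
        for _pop in range(2):
            if F > 0:
                a = ancestral * (1 - F) / F
                bpar = (1 - ancestral) * (1 - F) / F
                f = rng.beta(a, bpar)
            else:
                f = ancestral.copy()
            pop_freqs.append(np.clip(f, 1e-6, 1 - 1e-6))
        block_dos = np.empty((n_total, block.n_snps), dtype=float)
        offset = 0
        for pop, n_pop in enumerate((n_bud, n_man)):
            h1 = _block_haplotypes(rng, n_pop, pop_freqs[pop], block.ld_decay)
            h2 = _block_haplotypes(rng, n_pop, pop_freqs[pop], block.ld_decay)
            block_dos[offset:offset + n_pop] = h1 + h2
            offset += n_pop
        dosage_cols.append(block_dos)
        for j in range(block.n_snps):
            counter += 1
            meta_rows.append((
                f"snp{counter:05d}", block.chromosome,
                block.start_pos + j * block.spacing, "A", "G",
            ))

    dosages = np.concatenate(dosage_cols, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    meta = pd.DataFrame(
        meta_rows, columns=["snp_id", "chrom", "pos", "allele_a", "allele_b"]
    )
    ids = np.array(
        [f"{POP_LABELS[0]}_{i:05d}" for i in range(n_bud)]
        + [f"{POP_LABELS[1]}_{i:05d}" for i in range(n_man)],
        dtype=object,
    )
    return GenotypeMatrix(dosages, meta, ids)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    G: GenotypeMatrix,
    effects: Sequence[EffectSpec],
    config: CohortConfig,
) -> pd.DataFrame:
    """Draw phenotypes from the logistic liability.

    migraine ~ Bernoulli(expit(intercept + b_age·age_std + b_sex·female +
    b_pop·site + b_depr·DEPR + Σ b_main·g + Σ b_int·g·DEPR)); lifetime
    depression is Bernoulli(prevalence) independent of genotype.  Missing
    dosages are mean-imputed inside the liability only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n = G.n_individuals
    pop = np.array([0 if str(i).startswith(POP_LABELS[0]) else 1
                    for i in G.individual_ids])
    age = rng.uniform(18.0, 60.0, size=n)
    age_std = (age - age.mean()) / age.std()
    sex = rng.integers(1, 3, size=n)          # 1 male / 2 female
    prev = np.asarray(config.depression_prevalence)[pop]
    depr = (rng.random(n) < prev).astype(int)

    eta = (config.intercept
           + config.beta_age * age_std
           + config.beta_sex * (sex == 2)
           + config.beta_pop * pop
           + config.beta_depression * depr)
    for eff in effects:
        try:
            j = G.snp_index(eff.snp_id)
        except KeyError as exc:
            raise ConfigurationError(str(exc)) from exc
        g = G.dosages[:, j].copy()
        g[np.isnan(g)] = np.nanmean(g)
        eta = eta + eff.beta_main * g + eff.beta_interaction * g * depr
    migr = (rng.random(n) < expit(eta)).astype(int)

    pheno = pd.DataFrame({
        "IID": G.individual_ids,
        "MIGR": migr,
        "DEPR": depr,
        "SEX": sex,
        "AGE": np.round(age, 1),
        "POP": np.array(POP_LABELS, dtype=object)[pop],
    })
    return validate_phenotypes(pheno)


def write_cohort(G: GenotypeMatrix, pheno: pd.DataFrame, prefix: str | Path) -> None:
    """Emit ``<prefix>.ped``, ``<prefix>.map`` and ``<prefix>.pheno.tsv``."""
    prefix = Path(prefix)
    write_ped_map(G, pheno, prefix)
    write_phenotypes(pheno, prefix.parent / (prefix.name + ".pheno.tsv"))


def simulate_cohort(
    blocks: Sequence[BlockSpec] | None = None,
    effects: Sequence[EffectSpec] = (),
    config: CohortConfig | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Convenience wrapper: genotypes plus phenotypes in one call."""
    config = config or CohortConfig()
    blocks = list(blocks) if blocks is not None else default_blocks()
    G = simulate_genotypes(blocks, config)
    pheno = simulate_phenotypes(G, effects, config)
    return G, pheno
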