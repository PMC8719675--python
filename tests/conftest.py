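"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from gxemig.genio import GenotypeMatrix
from gxemig.synthetic_cohort import (
    BlockSpec, CohortConfig, EffectSpec, simulate_cohort, simulate_genotypes,
)


def make_genotypes(dosages, chrom="1", start=1000, spacing=1000, ids=None):
    """Hand-built GenotypeMatrix from a dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    meta = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": [chrom] * m,
        "pos": [start + j * spacing for j in range(m)],
        "allele_a": ["A"] * m,
        "allele_b": ["G"] * m,
    })
    if ids is None:
        ids = np.array([f"i{i}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosages, meta, np.asarray(ids, dtype=object))


@pytest.fixture(scope="session")
def small_cohort():
    """300 individuals x 60 SNPs, one main-effect and one interaction SNP."""
    cfg = CohortConfig(n_per_population=(150, 150), seed=42,
                       missing_rate=0.01, stratification_divergence=0.02)
    blocks = [
        BlockSpec(20, (0.2, 0.4), ld_decay=0.8, chromosome="1"),
        BlockSpec(40, (0.2, 0.4), ld_decay=0.0, chromosome="2",
                  start_pos=5_000_000),
    ]
    effects = [EffectSpec("snp00001", beta_main=0.5),
               EffectSpec("snp00021", beta_interaction=0.9)]
    return simulate_cohort(blocks, effects, cfg)


@pytest.fixture(scope="session")
def null_genotypes():
    """400 individuals x 200 independent SNPs, no structure, no missingness."""
    cfg = CohortConfig(n_per_population=(200, 200), seed=7,
                       missing_rate=0.0, stratification_divergence=0.0)
    return simulate_genotypes([BlockSpec(200, (0.1, 0.4), ld_decay=0.0)], cfg)
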