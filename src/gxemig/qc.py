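"""Genotype quality control on hard-call dosage matrices.

The cascade mirrors standard case-control GWAS practice on array data:

1. minor-allele-frequency filter (default 0.01);
2. iterative missingness filtering at decreasing thresholds
   (0.1 → 0.05 → 0.01), SNPs before individuals within each step;
3. exact Hardy–Weinberg test, excluding SNPs with p < 1e-5;
4. on an LD-pruned SNP subset (r² ≤ 0.2): identity-by-descent relatedness
   (π̂ ≤ 0.1875), heterozygosity outliers (|z| ≤ 3) and the first 10
   principal components of the standardized dosage matrix.

Pruning serves only relatedness/PCA; association analyses downstream use
the unpruned post-QC SNP set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from gxemig.genio import GenotypeMatrix


@dataclass(frozen=True)
class QcThresholds:
    maf_min: float = 0.01
    missingness_steps: tuple[float, ...] = (0.1, 0.05, 0.01)
    hwe_min_p: float = 1e-5
    prune_r2: float = 0.2
    ibd_max: float = 0.1875
    het_z_max: float = 3.0
    n_pcs: int = 10
    info_min: float = 0.5        # optional per-SNP imputation-quality filters
    certainty_min: float = 0.7

    def __post_init__(self) -> None:
        for p in (self.maf_min, self.hwe_min_p, self.prune_r2, self.ibd_max,
                  *self.missingness_steps):
            if not 0.0 < p < 1.0:
                raise ValueError("QC probability thresholds must lie in (0, 1)")
        steps = self.missingness_steps
        if any(a <= b for a, b in zip(steps, steps[1:])):
            raise ValueError("missingness steps must be strictly decreasing")


@dataclass
class QcReport:
    """Ordered log of QC steps with per-step removal counts."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, snps_removed: int = 0,
            individuals_removed: int = 0, **detail) -> None:
        self.steps.append({
            "step": name,
            "snps_removed": int(snps_removed),
            "individuals_removed": int(individuals_removed),
            **detail,
        })

    @property
    def total_snps_removed(self) -> int:
        return sum(s["snps_removed"] for s in self.steps)

    @property
    def total_individuals_removed(self) -> int:
        return sum(s["individuals_removed"] for s in self.steps)

    def to_json(self) -> str:
        return json.dumps(self.steps, indent=2)

    def __str__(self) -> str:
        lines = ["QC cascade:"]
        for s in self.steps:
            lines.append(
                f"  {s['step']}: -{s['snps_removed']} SNPs, "
                f"-{s['individuals_removed']} individuals"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Hardy–Weinberg
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy–Weinberg test p-value from genotype counts.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts no more probable than the observed one (the
    standard SNP-HWE exact test, as used by PLINK).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0:
        return 1.0
    # Enumerate heterozygote counts with the parity of n_rare.
    het_counts = np.arange(n_rare % 2, n_rare + 1, 2)
    log_probs = np.empty(len(het_counts))
    for i, h in enumerate(het_counts):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        log_probs[i] = (
            h * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma(h + 1) - math.lgamma(rare_hom + 1)
            - math.lgamma(common_hom + 1)
            + math.lgamma(n_rare + 1) + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    obs = probs[het_counts == n_Aa][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_chi2_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square Hardy–Weinberg test (no continuity correction)."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    exp = np.array([p * p, 2 * p * q, q * q]) * n
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    nonzero = exp > 0
    chi2 = float(((obs[nonzero] - exp[nonzero]) ** 2 / exp[nonzero]).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test(n_AA: int, n_Aa: int, n_aa: int,
             method: Literal["exact", "chi2"] = "exact") -> float:
    if method == "exact":
        return hwe_exact_test(n_AA, n_Aa, n_aa)
    if method == "chi2":
        return hwe_chi2_test(n_AA, n_Aa, n_aa)
    raise ValueError(f"unknown HWE method {method!r}")


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(n_effect_hom, n_het, n_ref_hom) over non-missing calls."""
    d = dosages[~np.isnan(dosages)]
    return int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())


def hwe_pvalues(G: GenotypeMatrix, method: str = "exact") -> np.ndarray:
    out = np.ones(G.n_snps)
    for j in range(G.n_snps):
        aa, ab, bb = genotype_counts(G.dosages[:, j])
        if aa + ab + bb == 0:
            out[j] = np.nan
        else:
            out[j] = hwe_test(aa, ab, bb, method=method)
    return out


# ---------------------------------------------------------------------------
# SNP / individual filters
# ---------------------------------------------------------------------------

def maf_filter(G: GenotypeMatrix, maf_min: float) -> tuple[GenotypeMatrix, int]:
    freqs = G.allele_frequencies()
    maf = np.minimum(freqs, 1 - freqs)
    keep = maf >= maf_min
    return G.subset(snps=keep), int((~keep).sum())


def iterative_missingness_filter(
    G: GenotypeMatrix, steps: tuple[float, ...] = (0.1, 0.05, 0.01),
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """At each threshold, first drop SNPs then individuals above it."""
    if any(a <= b for a, b in zip(steps, steps[1:])):
        raise ValueError("missingness steps must be strictly decreasing")
    report = report if report is not None else QcReport()
    for step in steps:
        keep_snps = G.snp_missingness() <= step
        n_snp_rm = int((~keep_snps).sum())
        if n_snp_rm:
            G = G.subset(snps=keep_snps)
        keep_ind = G.individual_missingness() <= step
        n_ind_rm = int((~keep_ind).sum())
        if n_ind_rm:
            G = G.subset(individuals=keep_ind)
        report.add(f"missingness<= {step}", n_snp_rm, n_ind_rm)
        if G.n_snps == 0 or G.n_individuals == 0:
            raise ValueError(f"matrix empty after missingness step {step}\n{report}")
    return G, report


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation over pairwise-complete dosage columns."""
    return pd.DataFrame(dosages).corr().to_numpy() ** 2


def ld_prune(G: GenotypeMatrix, r2_max: float = 0.2,
             window: int = 50, step: int = 5) -> list[str]:
    """Greedy windowed LD pruning; returns surviving SNP ids.

    Windows slide per chromosome in position order.  Within a window, while
    any kept pair has r² > ``r2_max``, the first offending pair (scan order)
    loses its lower-MAF member; MAF ties remove the higher position.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    freqs = G.allele_frequencies()
    maf = np.minimum(freqs, 1 - freqs)
    keep = np.ones(G.n_snps, dtype=bool)
    meta = G.snp_meta
    for chrom in meta["chrom"].unique():
        chrom_idx = meta.index[meta["chrom"] == chrom].to_numpy()
        chrom_idx = chrom_idx[np.argsort(meta.loc[chrom_idx, "pos"].to_numpy(),
                                         kind="stable")]
        start = 0
        while start < len(chrom_idx):
            win = chrom_idx[start:start + window]
            active = [j for j in win if keep[j]]
            changed = True
            while changed and len(active) > 1:
                changed = False
                r2 = _pairwise_r2(G.dosages[:, active])
                for a in range(len(active)):
                    for b in range(a + 1, len(active)):
                        if np.isfinite(r2[a, b]) and r2[a, b] > r2_max:
                            ja, jb = active[a], active[b]
                            if (maf[ja], -G.snp_meta.loc[ja, "pos"]) < \
                               (maf[jb], -G.snp_meta.loc[jb, "pos"]):
                                drop = ja
                            else:
                                drop = jb
                            keep[drop] = False
                            active.remove(drop)
                            changed = True
                            break
                    if changed:
                        break
            if start + window >= len(chrom_idx):
                break
            start += step
    return [meta.loc[j, "snp_id"] for j in range(G.n_snps) if keep[j]]


# ---------------------------------------------------------------------------
# Relatedness (method-of-moments IBD)
# ---------------------------------------------------------------------------

def pi_hat_matrix(G_pruned: GenotypeMatrix) -> np.ndarray:
    """Pairwise π̂ = P(IBD=1)/2 + P(IBD=2) from IBS counts.

    Uses the method-of-moments estimator on sample allele frequencies:
    observed IBS0/1/2 counts per pair are compared with their expectations
    under IBD states 0/1/2.  Estimates are clamped to [0, 1].
    """
    dos = G_pruned.dosages
    freqs = G_pruned.allele_frequencies()
    valid = np.isfinite(freqs) & (freqs > 0) & (freqs < 1)
    dos = dos[:, valid]
    p = freqs[valid]
    q = 1 - p

    obs = ~np.isnan(dos)
    A = [np.where(obs, dos == k, False).astype(float) for k in (0, 1, 2)]
    O = obs.astype(float)

    n_complete = O @ O.T
    ibs0 = A[0] @ A[2].T + A[2] @ A[0].T
    ibs2 = sum(a @ a.T for a in A)
    ibs1 = n_complete - ibs0 - ibs2

    # Expected per-SNP IBS probabilities given IBD state.
    p0_ibd0 = 2 * p**2 * q**2
    p1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    p2_ibd0 = 1 - p0_ibd0 - p1_ibd0
    p1_ibd1 = 2 * p * q
    p2_ibd1 = 1 - p1_ibd1

    e0_0 = (O * p0_ibd0) @ O.T
    e1_0 = (O * p1_ibd0) @ O.T
    e2_0 = (O * p2_ibd0) @ O.T
    e1_1 = (O * p1_ibd1) @ O.T
    e2_1 = (O * p2_ibd1) @ O.T

    # The intermediate P(IBD=k) solutions are left unclamped so that
    # sampling noise cancels in π̂; only the final estimate is clamped.
    with np.errstate(divide="ignore", invalid="ignore"):
        P0 = ibs0 / e0_0
        P1 = (ibs1 - P0 * e1_0) / e1_1
        P2 = (ibs2 - P0 * e2_0 - P1 * e2_1) / n_complete
    pihat = np.clip(P1 / 2 + P2, 0.0, 1.0)
    np.fill_diagonal(pihat, 1.0)
    return pihat


def ibd_filter(G_pruned: GenotypeMatrix, ibd_max: float = 0.1875) -> list[str]:
    """Individuals to remove so that no remaining pair has π̂ > ibd_max.

    For each offending pair (processed by decreasing π̂) the member with
    higher missingness is removed; ties remove the lexicographically later
    id.
    """
    n = G_pruned.n_individuals
    if n < 2:
        return []
    pihat = pi_hat_matrix(G_pruned)
    miss = G_pruned.individual_missingness()
    ids = G_pruned.individual_ids
    iu = np.triu_indices(n, k=1)
    offending = [(pihat[i, j], i, j) for i, j in zip(*iu) if pihat[i, j] > ibd_max]
    offending.sort(key=lambda t: (-t[0], t[1], t[2]))
    removed: set[int] = set()
    for _, i, j in offending:
        if i in removed or j in removed:
            continue
        if (miss[i], str(ids[i])) > (miss[j], str(ids[j])):
            removed.add(i)
        else:
            removed.add(j)
    return sorted((str(ids[i]) for i in removed))


def heterozygosity_outliers(G_pruned: GenotypeMatrix, z_max: float = 3.0) -> list[str]:
    """Individuals whose heterozygosity rate lies |z| > z_max from the mean."""
    if G_pruned.n_individuals < 10:
        raise ValueError("need at least 10 individuals for outlier detection")
    het = np.nanmean(G_pruned.dosages == 1, axis=1)
    sd = het.std()
    if sd == 0 or not np.isfinite(z_max):
        return []
    z = (het - het.mean()) / sd
    return [str(i) for i, zz in zip(G_pruned.individual_ids, z) if abs(zz) > z_max]


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------

def compute_pcs(G_pruned: GenotypeMatrix, n_pcs: int = 10) -> np.ndarray:
    """PC scores of the standardized dosage matrix (n_individuals × n_pcs).

    Each SNP is centred by 2p̂ and scaled by sqrt(2p̂(1−p̂)); missing
    dosages are mean-imputed (zero after centring) for this step only.
    Sign convention: the largest-magnitude SNP loading of each component is
    made positive.
    """
    freqs = G_pruned.allele_frequencies()
    usable = np.isfinite(freqs) & (freqs > 0) & (freqs < 1)
    X = G_pruned.dosages[:, usable]
    p = freqs[usable]
    X = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    X = np.where(np.isnan(X), 0.0, X)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((S > S[0] * 1e-9).sum()) if S.size else 0
    if n_pcs > rank:
        raise ValueError(f"requested {n_pcs} PCs but matrix rank is {rank}")
    scores = U[:, :n_pcs] * S[:n_pcs]
    loads = Vt[:n_pcs]
    for k in range(n_pcs):
        top = np.argmax(np.abs(loads[k]))
        if loads[k, top] < 0:
            scores[:, k] *= -1
    return scores


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def run_qc(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
    snp_quality: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, QcReport]:
    """Run the full cascade; returns the filtered matrix, the phenotype
    table restricted to surviving individuals with PC columns appended, and
    the step-by-step report."""
    report = QcReport()
    t = thresholds

    if snp_quality is not None:
        keep = np.asarray(snp_quality) >= t.info_min
        G = G.subset(snps=keep)
        report.add("imputation_quality", snps_removed=int((~keep).sum()))

    G, n_rm = maf_filter(G, t.maf_min)
    report.add(f"maf>={t.maf_min}", snps_removed=n_rm)

    G, report = iterative_missingness_filter(G, t.missingness_steps, report)

    hwe_p = hwe_pvalues(G)
    keep = ~(hwe_p < t.hwe_min_p)
    report.add(f"hwe_p>={t.hwe_min_p}", snps_removed=int((~keep).sum()))
    G = G.subset(snps=keep)

    pruned_ids = ld_prune(G, t.prune_r2)
    G_pruned = G.select_snps(pruned_ids)
    report.add(f"ld_prune r2<={t.prune_r2}", pruned_set_size=len(pruned_ids))

    to_remove = set(ibd_filter(G_pruned, t.ibd_max))
    if to_remove:
        keep_ind = ~np.isin(G.individual_ids.astype(str), sorted(to_remove))
        G = G.subset(individuals=keep_ind)
        G_pruned = G_pruned.subset(individuals=keep_ind)
    report.add(f"ibd<={t.ibd_max}", individuals_removed=len(to_remove))

    het_out = set(heterozygosity_outliers(G_pruned, t.het_z_max))
    if het_out:
        keep_ind = ~np.isin(G.individual_ids.astype(str), sorted(het_out))
        G = G.subset(individuals=keep_ind)
        G_pruned = G_pruned.subset(individuals=keep_ind)
    report.add(f"het|z|<={t.het_z_max}", individuals_removed=len(het_out))

    pcs = compute_pcs(G_pruned, t.n_pcs)
    pheno = pheno.set_index("IID", drop=False).loc[
        [str(i) for i in G.individual_ids]].reset_index(drop=True)
    for k in range(t.n_pcs):
        pheno[f"PC{k + 1}"] = pcs[:, k]
    report.add(f"pca n_pcs={t.n_pcs}")
    return G, pheno, report
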