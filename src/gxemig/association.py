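"""Per-SNP logistic association scans and the two-subsample replication rule.

Each SNP is tested in each analysis sample (the two cohorts separately and
pooled) with a logistic regression of migraine on the additive effect-allele
dosage, adjusting for age, sex and the first 10 principal components of the
sample's genotypes.  The interaction scan adds lifetime depression (DEPR)
and a SNP×DEPR product term and reports the product term.

A SNP *replicates* when its test term is nominally significant (p < 0.05)
in both cohorts and in the pooled sample, with the same effect allele and
the same effect direction throughout — a deliberately permissive rule for
candidate-SNP confirmation; no multiple-testing correction enters the pass
decision, though a Bonferroni column is emitted for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from gxemig.genio import AssociationRecord, GenotypeMatrix
from gxemig.qc import compute_pcs, genotype_counts, hwe_test

SAMPLES = ("BUD", "MAN", "TOTAL")
ALPHA = 0.05


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    converged: bool
    separated: bool
    loglik: float
    n: int


def fit_logistic(y: np.ndarray, X: np.ndarray, maxiter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic fit with two-tailed Wald p-values.

    Fitted by Newton/IRLS; non-convergence within ``maxiter`` iterations and
    (quasi-)perfect separation are flagged rather than raised, so callers
    can exclude the record from replication decisions.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(method="newton", maxiter=maxiter, disp=0,
                            warn_convergence=False)
            converged = bool(res.mle_retvals.get("converged", False))
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            k = X.shape[1]
            return LogisticFit(np.full(k, np.nan), np.full(k, np.nan),
                               np.full(k, np.nan), False, True, np.nan, len(y))
    se = np.asarray(res.bse)
    beta = np.asarray(res.params)
    # Huge estimates/SEs are the practical signature of separation.
    if not np.all(np.isfinite(se)) or np.any(np.abs(beta) > 15):
        separated = True
    z = np.where(se > 0, beta / se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    return LogisticFit(beta, se, p, converged, separated,
                       float(res.llf), int(len(y)))


def sample_masks(pheno: pd.DataFrame) -> dict[str, np.ndarray]:
    """Boolean masks for the two cohorts and the pooled sample."""
    pops = pheno["POP"].to_numpy()
    labels = sorted(pd.unique(pops))
    masks: dict[str, np.ndarray] = {}
    for canonical, lab in zip(SAMPLES[:2], labels):
        masks[canonical] = pops == lab
    masks["TOTAL"] = np.ones(len(pheno), dtype=bool)
    return masks


def _covariate_matrix(pheno: pd.DataFrame, pcs: np.ndarray) -> np.ndarray:
    age = pheno["AGE"].to_numpy(dtype=float)
    sex = (pheno["SEX"].to_numpy(dtype=float) == 2).astype(float)
    return np.column_stack([age, sex, pcs])


def _scan(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    mode: Literal["main", "interaction"],
    outcome: str = "MIGR",
    snp_ids: Sequence[str] | None = None,
    n_pcs: int = 10,
    pc_source: GenotypeMatrix | None = None,
    hwe_alpha: float = ALPHA,
) -> list[AssociationRecord]:
    test = "ADD" if mode == "main" else "ADDxDEPR"
    records: list[AssociationRecord] = []
    masks = sample_masks(pheno)
    pc_G = pc_source if pc_source is not None else G
    snp_idx = (range(G.n_snps) if snp_ids is None
               else [G.snp_index(s) for s in snp_ids])
    meta = G.snp_meta
    y_all = pheno[outcome].to_numpy(dtype=float)
    depr_all = pheno["DEPR"].to_numpy(dtype=float)

    for sample, mask in masks.items():
        pcs = compute_pcs(pc_G.subset(individuals=mask), n_pcs)
        cov = _covariate_matrix(pheno.loc[mask], pcs)
        y_s = y_all[mask]
        depr_s = depr_all[mask]
        dos_s = G.dosages[mask, :]
        for j in snp_idx:
            g = dos_s[:, j]
            row = meta.iloc[j]
            base = dict(snp_id=row.snp_id, sample=sample, test=test,
                        effect_allele=row.allele_a, chrom=str(row.chrom),
                        pos=int(row.pos))
            obs = ~np.isnan(g)
            n_used = int(obs.sum())
            gg = g[obs]
            if len(np.unique(gg)) < 2:
                records.append(AssociationRecord(
                    **base, n_used=n_used, beta=np.nan, se=np.nan, p=np.nan,
                    flag="monomorphic"))
                continue
            # per-sample Hardy-Weinberg exclusion at the analysis stage
            if hwe_test(*genotype_counts(gg)) < hwe_alpha:
                records.append(AssociationRecord(
                    **base, n_used=n_used, beta=np.nan, se=np.nan, p=np.nan,
                    flag="hwe_excluded"))
                continue
            if mode == "main":
                X = np.column_stack([np.ones(n_used), gg, cov[obs]])
                term = 1
            else:
                d = depr_s[obs]
                X = np.column_stack(
                    [np.ones(n_used), gg, d, gg * d, cov[obs]])
                term = 3
            try:
                fit = fit_logistic(y_s[obs], X)
            except ValueError:
                records.append(AssociationRecord(
                    **base, n_used=n_used, beta=np.nan, se=np.nan, p=np.nan,
                    flag="nonconverged"))
                continue
            flag = ""
            if fit.separated:
                flag = "separation"
            elif not fit.converged:
                flag = "nonconverged"
            records.append(AssociationRecord(
                **base, n_used=n_used, beta=float(fit.beta[term]),
                se=float(fit.se[term]), p=float(fit.p[term]), flag=flag))
    return records


def run_main_scan(G, pheno, snp_ids=None, n_pcs=10, pc_source=None):
    """ADD records for every SNP in BUD, MAN and TOTAL."""
    return _scan(G, pheno, "main", snp_ids=snp_ids, n_pcs=n_pcs,
                 pc_source=pc_source)


def run_interaction_scan(G, pheno, snp_ids=None, n_pcs=10, pc_source=None):
    """ADDxDEPR records (SNP, DEPR and SNP×DEPR in the model; the product
    term is reported) for every SNP in BUD, MAN and TOTAL."""
    return _scan(G, pheno, "interaction", snp_ids=snp_ids, n_pcs=n_pcs,
                 pc_source=pc_source)


def depression_outcome_check(G, pheno, hit_snps: Sequence[str],
                             n_pcs=10, pc_source=None) -> pd.DataFrame:
    """Test hit SNPs for a main effect on lifetime depression (pooled
    sample, same covariates); returns records with a ``flagged`` column for
    p < 0.05."""
    if not hit_snps:
        return pd.DataFrame(columns=["snp_id", "beta", "p", "flagged"])
    records = _scan(G, pheno, "main", outcome="DEPR", snp_ids=list(hit_snps),
                    n_pcs=n_pcs, pc_source=pc_source)
    rows = [r for r in records if r.sample == "TOTAL"]
    return pd.DataFrame({
        "snp_id": [r.snp_id for r in rows],
        "beta": [r.beta for r in rows],
        "p": [r.p for r in rows],
        "flagged": [r.ok and r.p < ALPHA for r in rows],
    })


# ---------------------------------------------------------------------------
# Replication criterion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicationRecord:
    snp_id: str
    test: str
    records: Mapping[str, AssociationRecord]   # keyed BUD/MAN/TOTAL
    passed: bool
    direction: str | None                      # "risk" / "protective"
    reason: str = ""


def apply_replication_criterion(
    records: Iterable[AssociationRecord], alpha: float = ALPHA,
) -> list[ReplicationRecord]:
    """Pass ⇔ p < alpha in BUD, MAN and TOTAL with the same effect allele
    and the same sign of beta; direction taken from the pooled OR."""
    by_key: dict[tuple[str, str], dict[str, AssociationRecord]] = {}
    for r in records:
        by_key.setdefault((r.snp_id, r.test), {})[r.sample] = r
    out: list[ReplicationRecord] = []
    for (snp_id, test), per_sample in sorted(by_key.items()):
        missing = [s for s in SAMPLES if s not in per_sample]
        if missing:
            out.append(ReplicationRecord(snp_id, test, per_sample, False,
                                         None, f"missing sample {missing}"))
            continue
        rs = [per_sample[s] for s in SAMPLES]
        if any(not r.ok for r in rs):
            out.append(ReplicationRecord(snp_id, test, per_sample, False,
                                         None, "flagged fit"))
            continue
        if len({r.effect_allele for r in rs}) != 1:
            out.append(ReplicationRecord(snp_id, test, per_sample, False,
                                         None, "effect allele differs"))
            continue
        if any(not (r.p < alpha) for r in rs):
            out.append(ReplicationRecord(snp_id, test, per_sample, False,
                                         None, "not significant in all samples"))
            continue
        signs = {np.sign(r.beta) for r in rs}
        if len(signs) != 1 or 0.0 in signs:
            out.append(ReplicationRecord(snp_id, test, per_sample, False,
                                         None, "effect direction differs"))
            continue
        direction = "risk" if per_sample["TOTAL"].beta > 0 else "protective"
        out.append(ReplicationRecord(snp_id, test, per_sample, True, direction))
    return out


def replication_table(results: Sequence[ReplicationRecord],
                      n_tests: int | None = None) -> pd.DataFrame:
    """Tabular view of replication results with a Bonferroni column."""
    n_tests = n_tests or max(len(results), 1)
    rows = []
    for rr in results:
        row: dict = {"snp_id": rr.snp_id, "test": rr.test, "pass": rr.passed,
                     "direction": rr.direction, "reason": rr.reason}
        for s in SAMPLES:
            r = rr.records.get(s)
            row[f"p_{s}"] = r.p if r else np.nan
            row[f"OR_{s}"] = r.odds_ratio if r and np.isfinite(r.beta) else np.nan
        tot = rr.records.get("TOTAL")
        row["p_TOTAL_bonferroni"] = (min(1.0, tot.p * n_tests)
                                     if tot and np.isfinite(tot.p) else np.nan)
        rows.append(row)
    columns = (["snp_id", "test", "pass", "direction", "reason"]
               + [f"{m}_{s}" for s in SAMPLES for m in ("p", "OR")]
               + ["p_TOTAL_bonferroni"])
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)
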