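# gxemig

Candidate-SNP analysis of migraine that separates variants acting on
migraine *in general* from variants acting *only in people with lifetime
depression*, for genetic-epidemiology researchers working with two-site
case-control questionnaire cohorts.

The pipeline chains five analyses:

1. **Genotype QC** — MAF ≥ 0.01, iterative missingness (0.1/0.05/0.01),
   exact Hardy–Weinberg test (p ≥ 1e-5), LD pruning (r² ≤ 0.2),
   identity-by-descent relatedness (π̂ ≤ 0.1875), heterozygosity outliers,
   and 10 principal components.
2. **Association scans** — per-SNP logistic regression of migraine on the
   effect-allele dosage with age, sex and 10 PCs as covariates, for the
   main effect (`ADD`) and for the SNP×depression interaction
   (`ADDxDEPR`, from a model with SNP + DEPR + SNP·DEPR).  A SNP
   *replicates* when p < 0.05 with the same effect allele and direction in
   both cohorts and the pooled sample.
3. **LD clumping** — replicated hits reduced to one index SNP per block
   (r² > 0.6 joins a clump; greedy by ascending p).
4. **Bayesian relevance analysis** — Metropolis–Hastings over Bayesian
   network structures (≤ 5 parents, uniform structure prior,
   Cooper–Herskovits/K2 parameter prior); the posterior probability that a
   variable lies in migraine's Markov blanket is its *strong relevance*.
   Run separately in depressed and non-depressed subjects, the per-SNP
   relevance difference quantifies depression-conditional genetic effects.
5. **Predictive power** — nested feature ladders (M0 demographics;
   M1 + main-effect SNPs; M2 + depression; M3 + interaction SNPs) scored
   by a 10+10-unit ReLU network (Adam, batch 20, 50 epochs) under 10×10
   stratified cross-validation with a sensitivity/specificity-weighted
   accuracy, confirmed by a logistic-regression ladder compared by AIC.

The original cohorts are not deposited, so the package includes a
first-class synthetic-cohort generator (haploblock LD via thresholded
AR(1) latent Gaussians, Balding–Nichols site divergence, logistic
liability with SNP main effects and SNP×depression interactions) that
reproduces the study design at desk scale: two cohorts of 839 + 976
individuals, ~1000 SNPs including one very large haploblock.  See
`docs/methods.md` for the model details and the respects in which the
synthetic data are simpler than real array data.

## Worked example

```python
from gxemig.pipeline import default_config, run_pipeline

report = run_pipeline(default_config(seed=1), "out")
for row in report["table_predictive_power"]:
    print(row["model"], round(row["score"], 3),
          None if row["diff_vs_M0_pct"] != row["diff_vs_M0_pct"]
          else f'{row["diff_vs_M0_pct"]:+.1f}%')
```

On the default simulated study (seed 1, two simulated main-effect SNPs
with OR ≈ 1.6/0.6 and three interaction-only SNPs with stratum OR ≈ 3)
this prints, after QC, both scans, replication and clumping:

```
M0 0.581 None
M1 0.587 +1.1%
M2 0.772 +33.0%
M3 0.772 +33.0%
```

M0 (age, sex, site) predicts migraine barely above chance; adding
lifetime depression (M2) lifts the weighted accuracy by a third —
depression is the dominant predictor, as in the study being emulated —
and the interaction SNPs (M3) add little on top at this sample size.
The same run's report also contains the replicated-hit tables
(`table_main_effects`, `table_interaction_clumped`), the stratified
relevance posteriors (in the run above the strongest interaction SNP
reaches a depressed-minus-non-depressed relevance difference of 0.98),
and the AIC ladder, which orders M3 < M2 < M1 < M0 as expected when
genuine interactions are present.  `out/report.md` holds the same tables
in readable form.

The command line mirrors the library:

```bash
gxemig simulate --out cohort --seed 1
gxemig qc --in cohort --pheno cohort.pheno.tsv --out cohort_qc
gxemig assoc --in cohort_qc --pheno cohort_qc.pheno.tsv --mode interaction --out int.tsv
gxemig run --out results/           # full pipeline, one config
```

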