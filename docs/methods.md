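# Methods

`gxemig` re-implements, as a tested and reusable pipeline, a candidate-SNP
case-control analysis that separates genetic variants acting on migraine in
everyone from variants acting only in people who report lifetime
depression.  The original cohorts are not public, so the package ships a
synthetic-cohort generator that reproduces the study's structure; every
downstream stage is exercised end to end on generated data.

## The analysis chain

1. **Quality control** of hard-call genotypes.
2. **Per-SNP logistic scans** for main effects and SNP×depression
   interactions in two cohorts and the pooled sample, with a
   dual-subsample replication rule.
3. **LD clumping** of replicated hits to one index SNP per block.
4. **Bayesian-network relevance analysis**: posterior probability of
   Markov-blanket membership with respect to migraine, overall and
   stratified by depression status.
5. **Predictive power** of nested feature sets via a small neural
   classifier under repeated cross-validation, confirmed with a logistic
   AIC ladder.

## Synthetic cohorts

Two populations (839 and 976 individuals by default, 1815 in total) are
generated per run.

*Genotypes.*  SNPs are organised in haploblocks.  Within a block, each
haplotype is a latent AR(1) Gaussian with adjacent correlation `ld_decay`,
thresholded at each SNP's allele-frequency quantile; two haplotypes sum to
a dosage in {0, 1, 2}.  `ld_decay = 0` gives independent SNPs and
`ld_decay = 1` makes the block one perfect proxy set.  Between-population
divergence follows a Balding–Nichols model: population frequencies are
Beta-distributed around the ancestral MAF with variance parameter
`stratification_divergence` (default 0.01, a realistic within-Europe
F_ST).  Genotypes are missing completely at random (default 0.5%).

The default panel holds ~1000 SNPs: one 120-SNP block with high LD
(emulating a megabase-scale intergenic haploblock), a 60-SNP gene-sized
block, two 15-SNP blocks on other chromosomes, and 800 unlinked background
SNPs.  The background must be a few hundred SNPs at minimum: the
method-of-moments relatedness estimate used in QC has sampling noise
~1/√m over m pruned SNPs, and with panels much below ~500 SNPs the fixed
π̂ ≤ 0.1875 threshold starts flagging unrelated pairs by chance.  The same
quantization applies to the 1% missingness step.  This is the main respect
in which desk-scale runs differ from an array-scale study; the thresholds
themselves are never adjusted.

*Phenotypes.*  Age is uniform 18–60 (the recruitment range) and
standardized inside the liability; sex is Bernoulli(½) coded 1/2;
lifetime depression is Bernoulli(prevalence, default 0.30) **independent
of genotype** — the emulated study found no genetic main effects on
depression, and this choice makes the depression-outcome check a true
negative control.  Migraine is Bernoulli with logit

```
intercept + b_age·age_std + b_sex·female + b_pop·site + b_depr·DEPR
          + Σ_s b_main,s·g_s + Σ_s b_int,s·g_s·DEPR
```

Defaults: intercept −1.4, b_depr = log 3, weak demographic effects —
migraine prevalence ≈ 0.27 with depression as the dominant predictor,
matching the qualitative finding that lifetime depression is the single
best predictor of migraine status.  The default demonstration effects are
two main-effect SNPs (OR ≈ 1.6 and 0.6) and three interaction-only SNPs
(stratum OR ≈ 3).  Published interaction ORs for such designs run from
~1.6 to ~6.6; the defaults sit in the upper half because a power
calculation shows the dual-subsample replication rule (p < 0.05 three
times with consistent direction) needs interaction log-odds ≳ 1 to have
realistic power at n = 1815 with ~30% exposure.

What the generator does **not** model: imputation uncertainty (all calls
are hard), recombination maps, sex chromosomes, genotype-dependent
missingness, and depression misclassification.  Passing tests therefore
demonstrate the correctness of the machinery and its calibration under
MCAR hard-call data, not robustness to those real-data complications.

## Quality control

Cascade (fixed order, every step logged with removal counts):
MAF ≥ 0.01 → iterative missingness (SNPs then individuals at 0.1, 0.05,
0.01) → exact Hardy–Weinberg test p ≥ 1e-5 → on an LD-pruned subset
(r² ≤ 0.2, 50-SNP window, step 5): relatedness (π̂ ≤ 0.1875, removing the
higher-missingness member of each pair), heterozygosity outliers
(|z| > 3) and the first 10 principal components.  Association runs on the
unpruned post-QC SNP set; pruning serves only relatedness and PCA.
Within each missingness step SNPs are filtered before individuals (the
convention of the standard published protocol; the alternative order is a
one-line change).

The Hardy–Weinberg test is the exact conditional test (sum of
probabilities of heterozygote counts no more probable than observed given
the allele counts), the PLINK default; a 1-df chi-square fallback is
selectable.  The exact p-value is validated against an independent
enumeration with `math.comb` rational arithmetic.

Relatedness: per-pair IBS0/1/2 counts are compared with their
expectations under IBD states computed from sample allele frequencies;
the moment solutions for P(IBD = k) are deliberately **not** clamped
individually (clamping biases π̂ upward by preventing error
cancellation) — only the final π̂ = P(IBD=1)/2 + P(IBD=2) is clamped to
[0, 1].

PCA standardizes each SNP by its 2p̂ mean and √(2p̂(1−p̂)) scale,
mean-imputes missing entries for this step only, and fixes signs by
making each component's largest-magnitude loading positive.

## Association scans and replication

Per SNP and analysis sample (each cohort separately, then pooled), a
logistic regression of migraine on effect-allele dosage with age, sex and
the sample's first 10 PCs as covariates; the interaction model adds DEPR
and the SNP×DEPR product and reports the product term.  Fits use
Newton/IRLS maximum likelihood with two-tailed Wald tests; non-convergence
and (quasi-)separation are flagged and excluded from replication
decisions.  Effect alleles are fixed once as the minor allele of the total
sample so "same effect allele" is well defined across subsamples.  SNPs
with within-sample exact HWE p < 0.05 are excluded per sample at analysis
time (separate from the QC-time 1e-5 filter).  PCs are recomputed per
analysis sample.

A SNP replicates when its test term has p < 0.05 in both cohorts and the
pooled sample with the same effect allele and effect direction.  No
multiple-testing correction enters the pass rule — this mirrors the
deliberately permissive confirmation design for pre-selected candidate
loci — but a Bonferroni-adjusted pooled p is emitted alongside.  Under a
global null the probability of passing is far below 0.05 because the two
cohort tests are independent; the suite asserts a pass fraction ≤ 1% over
2000 null SNPs.

## LD clumping

Replicated SNPs sorted by pooled p (ties by position); the best unassigned
SNP becomes an index and absorbs every unassigned SNP with dosage
r² > 0.6.  No physical-distance window by default (the blocks of interest
can be megabases wide).  Index selection by smallest p is the PLINK
default; the alternative positional rule is configurable upstream by
re-sorting the records.

## Bayesian-network relevance

Variables: the clumped SNPs (3-state dosels), age tertiles, sex,
population, DEPR (main analysis only) and migraine; complete-case rows.
The 10 PCs stay out of the network — the published variable list for this
step names only sex, age and the population descriptor, with population
substructure carried by the discrete site variable.

Structure posterior: uniform prior over DAGs with ≤ 5 parents per node;
parameter prior Cooper–Herskovits, i.e. Dirichlet with all hyperparameters
1, giving the K2 marginal likelihood per family

```
∏_j  (r−1)! / (N_j + r − 1)!  ·  ∏_k N_jk!
```

(j ranges over parent configurations, r child states, N_jk counts).  The
score is validated against an independent Pólya-urn sequential-prediction
evaluation of the same Dirichlet-multinomial integral.

Sampling: Metropolis–Hastings over DAGs with add/delete/reverse edge
moves proposed uniformly over the valid moves of the current structure;
the acceptance ratio multiplies the posterior ratio by the valid-move
count ratio (Hastings correction).  Family scores are cached, so a move
re-scores at most two families.  Every post-burn-in state contributes one
sample (no thinning); chains are pooled by sample-weighted averaging, and
the max–min spread of the per-variable posterior across chains is reported
as a convergence heuristic (reported, not enforced; < 0.05 is the
informal target).

A variable is *strongly relevant* when it lies in migraine's Markov
blanket (parents ∪ children ∪ children's other parents); "interaction
pattern with the target" is operationalized as this spouse membership.
The stratified analysis re-runs the full MCMC separately in depressed and
non-depressed subjects (DEPR removed from the variable set) and reports
relevance(depressed) − relevance(non-depressed) per SNP.

Step counts: the production-scale preset (1M burn-in + 2M sampling,
4 chains) is available as `McmcConfig.paper_scale()`; default runs use
20k + 100k with 4 chains, and the pipeline configuration uses 5k + 25k —
the MCMC is validated not by step count but by agreement (±0.03) with
exact posteriors computed by enumerating all DAGs on ≤ 4 variables.

Priors matter at small variable counts: with few nodes the uniform
structure prior places substantial mass on edges (2/3 for two isolated
nodes), so "irrelevant" variables plateau at a nonzero prior-driven
baseline rather than at 0.  Comparisons should be made against that
baseline or between strata, as the stratified difference does.

## Predictive power

Ladder: M0 = {age, sex, population}; M1 = M0 ∪ main-effect SNPs;
M2 = M0 ∪ DEPR; M3 = M2 ∪ interaction SNPs (dosages only — the network
learns interactions implicitly; explicit products appear only in the
logistic ladder).  Classifier: fully connected 10-unit input and hidden
layers, ReLU, logistic output, binary cross-entropy, Adam, batch 20, 50
epochs (scikit-learn's MLPClassifier; its Glorot-uniform initialization is
the uniform-family init used here).  Evaluation: stratified 10-fold CV
repeated 10 times; the score is w·sensitivity + (1−w)·specificity
averaged over the 100 test folds.

The weighting `w` is the test-fold case fraction by default, with a
balanced w = ½ variant selectable.  The two differ in their chance level:
under case-fraction weighting an uninformed classifier scores the
majority-class share, under balanced weighting it scores 0.5 regardless
of prevalence.  Null-calibration checks therefore run at balanced
prevalence (where both variants sit at 0.5); both variants can be
reported when prevalence is skewed.

Scaling is fit on each training fold only (age min–max from the training
fold, dosages divided by 2, binary features as 0/1) so no test
information leaks into training.  Folds whose test part is single-class
are skipped and counted.

The logistic confirmation fits the same ladder with explicit SNP×DEPR
products in M3, compares AICs (2k − 2·loglik) and reports per-term Wald
p-values, plus single-SNP M3 variants (one SNP's main + product pair at a
time).

## Numerical choices and degenerate inputs

* Monomorphic SNPs, non-converged fits (100 Newton iterations) and
  separated fits are flagged records, never silent drops; flagged records
  fail replication with a reason.
* HWE exact test with zero total count raises; monomorphic counts give
  p = 1.
* LD pruning tie-break: equal MAF keeps the lower position.  IBD removal
  tie-break: equal missingness removes the lexicographically later id.
* PCA raises if more components are requested than the matrix rank.
* Empty strata, empty hit lists and missing SNP ids raise or skip with
  explicit messages as documented per function.
* All randomness flows from integer seeds through `numpy` seed sequences;
  reruns with the same configuration are bit-identical (asserted for the
  full pipeline report).

## Known limitations

* The relatedness and missingness thresholds are calibrated for
  array-scale panels; at a few hundred SNPs they over-remove (documented
  above, and the reason the default synthetic panel is ~1000 SNPs).
* Structure MCMC is exact-validated only up to 4 variables; for the ~10
  variables of a real run, the per-chain spread is the only convergence
  diagnostic.
* The predictive scores of desk-scale runs carry Monte-Carlo noise from
  both fold assignment and network initialization; only differences well
  beyond the per-fold spread are meaningful.
* Imputation, phasing, dosage-probability formats, VCF/BGEN and
  functional annotation are out of scope.
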