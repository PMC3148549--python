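# Methods

## Problem and overall design

The package models a two-stage genetic risk-prediction study of severe
asthma exacerbations (any emergency-room visit or hospitalization) in
childhood asthmatics. A training cohort of 417 children (127 cases, 30%)
with genome-wide SNP genotypes and four clinical covariates is used to (i)
screen SNPs by random-forest importance and (ii) build vote-fraction
prediction models; an independent replication cohort of 164 children (50
cases, 30%) genotyped later is used only for evaluation. The original study
cohort is not publicly deposited, so the package ships a synthetic-cohort
generator with the same design parameters, and every pipeline stage is
exercised and tested on synthetic data.

## Random-forest screening and prediction

**Forests.** All models are ensembles of bagged classification trees with
Gini splits and `mtry = floor(sqrt(p))` candidate features per split
(scikit-learn's `RandomForestClassifier` underneath). The production tree
count is `ntree = 1500`, large enough that vote fractions are stable; the
desk-scale analyses and heavy tests use `ntree = 300` to keep runs short.
The per-sample prediction score is the fraction of the ensemble's trees
voting "case" — a majority vote per tree, not the average of per-tree class
probabilities — so scores live on a grid of step `1/ntree` in [0, 1].

**Two-step screening.** Stage 1 partitions the SNP panel, in chromosomal
order, into consecutive chunks of 4,000 SNPs (the last chunk smaller) and
fits one forest per chunk with that chunk's SNPs as the only predictors
(clinical covariates enter only at the prediction stage). Per-SNP scores
from all chunks are pooled into one genome-wide ranking. Stage 2 refits a
single forest on the top 4,000 SNPs jointly and re-ranks them; prediction
models use the stage-2 top k for k in {10, 40, 160, 320} (configurable).
Chunk scores are compared on their raw scale across chunks; this mirrors
the screening procedure being modelled and is a procedural choice, not a
statistical endorsement. For raw-scale comparability the impurity
importance is the *unnormalized* mean Gini decrease per feature averaged
over trees (a forest-normalized importance would inflate scores in a
smaller final chunk). Out-of-bag permutation importance (mean OOB accuracy
drop under feature permutation) is available as a configuration
alternative; the two measures agree on which strongly causal SNPs rank
first but not on fine ordering.

**Seeds.** Every chunk's forest seed derives from
`SeedSequence([master_seed, stage, chunk_index])`, so results are
bit-reproducible given the master seed and independent of how chunks are
scheduled.

**Prediction models.** A model is a forest over the selected k SNP columns
(additive minor-allele counts 0/1/2) concatenated with the four clinical
covariates — age (years), sex (1 = male, 2 = female), pre-bronchodilator
FEV1 % predicted, treatment group (1/2/3) — unless the SNPs-only variant is
requested. k = 0 (clinical-only) is always included in the ladder so the
clinical-baseline comparison is available. Internal cross-validation is a
single stratified 90/10 split per seed; stratification by outcome keeps
both classes in the 10% fold at n = 417 with 30% prevalence. A repeat count
is configurable but defaults to one split, matching the procedure being
emulated.

**Missing genotypes.** Forests require complete features, so missing calls
are imputed by drawing from each SNP's genotype frequency distribution
among the *training controls* (the non-exacerbation stage-1 samples), never
from cases or from the replication stage. The same rule covers training
missingness. A SNP with no non-missing control calls falls back to the
pooled genotype distribution over all control cells (with a warning).
Clinical covariates are never imputed; a missing covariate is an error.

## Evaluation

AUC is the Mann-Whitney statistic P(score_case > score_control) + ½ P(tie),
computed from ranks; it equals the trapezoidal area under the ROC curve
(tested to 1e-12 against a brute-force pairwise oracle). The standard error
is Hanley-McNeil. The p-value against chance uses the null variance of the
Mann-Whitney statistic, `n1·n0·(n1+n0+1)/12` on the U scale, with a normal
approximation and a continuity correction of 0.5; an exact mode enumerates
all label assignments when there are at most 10,000 (otherwise samples
them). With the continuity correction the normal p agrees with the exact
permutation p to well within 20% for moderate tails (exact p ≳ 0.05) at
n per class as small as 5; in deep tails (exact p ≲ 0.01) at such tiny n no
normal approximation tracks the discrete permutation distribution closely,
and the exact mode should be used. Operating-point PPV/NPV follow Bayes'
rule from (sensitivity, specificity, prevalence); at (0.2, 0.95, 0.3) the
NPV is 0.7348 and the PPV 0.6316.

## Null controls

The permutation control permutes training outcome labels uniformly, re-runs
SNP selection *and* model building end-to-end on the permuted labels, and
scores the untouched replication samples; re-running selection inside each
iteration is the default because reusing the original SNP list would leak
selection signal into the null. A `reuse_selection` flag provides the
cheaper variant. The random-SNP control draws k SNPs uniformly without
replacement from the panel. Both run 10 iterations by default and report
per-iteration and mean AUC.

## Synthetic cohort generator

Genotypes are independent SNPs in Hardy-Weinberg proportions with per-SNP
MAF uniform on (0.05, 0.5]; SNPs are laid out over 22 chromosomes in
contiguous blocks with increasing positions. Disease risk is logistic:
log-odds additive in minor-allele counts for the planted causal SNPs
(defaults: 20 SNPs, effects spread over 1.0–2.0 per allele), plus optional
pairwise genotype-product interaction terms, plus small covariate effects
(age −0.06/yr, sex −0.20, FEV1 −0.004/%, treatment +0.18/step) chosen so
the clinical-only model has weak but non-zero discrimination, matching the
qualitative clinical-baseline behaviour of such cohorts. The intercept is
calibrated by bisection so the expected case fraction equals the target
prevalence (default 0.30) within 0.005. Covariates: age ~ N(8.7, 2.1)
truncated above 5 (the truncation raises the realized mean by ≈0.19 y —
tests compare against the analytic truncated-normal mean), FEV1 ~ N(93.3,
14.0) truncated above 40, sex Bernoulli(male 0.63), treatment uniform on
{1,2,3}. Both stages are drawn from one generative law on one SNP panel and
split 417/164 by default. Missingness is uniform at a configurable rate.

What the generator does **not** emulate: linkage disequilibrium (an
optional block-copy LD mode was considered and dropped as out of the
asserted scope), population structure, genotyping error, informative
missingness, and covariate-genotype correlation. Passing tests therefore
demonstrate that the pipeline's machinery is correct and well calibrated
under its own assumptions, not that real exacerbation cohorts would yield
any particular AUC.

## Numerical and interface choices

- Genotype coding is additive 0/1/2 in the counted (minor) allele; the
  counted allele is the empirical minor allele with lexicographic
  tie-break, so re-reading a written file can flip the coding of a SNP
  whose sample frequency crosses 0.5 — at MAF ≤ 0.4 and the cohort sizes
  used this does not occur.
- The `.map` dialect carries no allele columns; monomorphic SNPs write the
  observed allele for every call and round-trip without loss.
- Missing genotypes are the integer sentinel −1 in matrices and NaN in the
  encoded float feature block; `0 0` on disk.
- Prevalence calibration fails loudly (rather than clamping) when the
  requested prevalence is unattainable given extreme effect sizes.
- Desk-scale problem sizes used by the shipped analyses and heavy tests:
  1,000–5,000 SNPs, 400–417 training samples, ntree 300, 10 control
  iterations / 10 seeds — chosen as the smallest sizes at which the
  calibration and recovery behaviour of interest is clearly visible.

## Known limitations

- Raw-scale pooling of importance scores across chunks (inherited from the
  modelled procedure) makes stage-1 ranks sensitive to chunk composition.
- The single 90/10 internal CV split has high variance; the configurable
  repeat count mitigates this when desired.
- The normal-approximation AUC p-value is anti-conservative in deep tails
  at very small n; use the exact mode there.
- Vote-fraction scores are not calibrated probabilities.
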