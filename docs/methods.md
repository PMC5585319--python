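# Methods

This note documents the statistical procedures implemented in `lncsig`,
the defaults and units of the parameters that matter, what the synthetic
generator does and does not emulate, and the choices made where the design
was genuinely open.

## Quality control

Samples are gated before normalization.

* **Hemolysis** is called when any of the absorbances A414, A541, A576
  (optical-density units) *strictly* exceeds 0.2; a missing reading makes
  the sample "not assessable" rather than silently passing. Hemolysis is
  recorded but never excludes a sample on its own; instead the pipeline
  compares erythrocyte contamination between cohorts (Fisher exact test on
  the hemolysis flag for frequency; two-sided Mann–Whitney on log2 of the
  summed erythrocyte + WBC marker counts for amount — the amount statistic
  is not specified by any convention we must match, and the rank-sum test
  was chosen for robustness to the heavy right tail of contamination
  counts).
* **Dilution factors** for the multiplexed target enrichment product target
  post-dilution Cq values of 16 (*GNAS*) and 19 (*VIM*). The model assumes
  100% PCR efficiency, i.e. one Cq cycle = a factor of 2, so the candidate
  factor is `2^(target − Cq)` when Cq is below target and 1 otherwise
  (samples already above target are not diluted); the larger candidate is
  used, to protect against cartridge overloading. The factor is therefore
  always ≥ 1 and nonincreasing in each Cq.
* **Binding density** must lie in [0.05, 2.25] spots/µm². The bounds are
  treated as inclusive ("between" read inclusively, so samples sitting at
  the window edge pass).
* **Exclusion** removes only amplification failures and binding-density
  failures; it is a pure row filter (counts of retained samples are
  untouched) and the report's retained + excluded counts always sum to the
  input size. An empty retained set is a hard error.

## Normalization

For each sample the background cut-point is `mean + 2·SD` of the negative
control probes (sample SD, n−1 denominator; at least two negatives are
required or the SD is undefined). Endogenous counts are background-
subtracted and clipped at zero. A probe is retained when its *raw* count
exceeds the sample's cut-point in at least 20% of samples — detection is
judged on raw counts so the filter does not depend on the clipping choice;
exactly 20% is retained ("fewer than 20%" removes).

Housekeeping scaling: per-sample geometric mean `g_s` of *ACTB*, *PGK1*,
*PPIB* on **raw** counts; cohort reference `G` = arithmetic mean of the
`g_s` (the platform vendor's convention); scale factor `f_s = G / g_s`;
normalized value `log2(corrected · f_s + 1)`. Raw housekeeping counts are
used because the background cut-point is an endogenous detection floor —
subtracting it from the stable genes would destroy the scale they define
(and zero them out entirely in low-count plasma data). The pseudocount of 1
is required because clipped zeros exist; with it, a zero corrected count
maps exactly to 0 on the log2 scale. Spike-in probes (*NEFL*, *ENO2*,
*GFAP*) are carried through and reported but never used for scaling, since
the housekeeping genes are the less variable set. Whether background-
corrected values should be allowed to go negative before the log transform
is not fixed by any convention; clipping plus pseudocount was chosen and is
recorded in the normalization provenance.

The `NCounterNormalizer` estimator freezes the detection-filtered probe
list and the reference geometric mean at `fit` time, so transforming new
samples is a proper prospective operation; with zero-variance negatives at
zero, scaling an entire sample row by a constant leaves its normalized
values exactly unchanged.

## Differential abundance

Per probe, a two-group comparison on the log2 scale with residual variance
`s²` on `d = n1 + n2 − 2` degrees of freedom. The empirical-Bayes prior
`(d0, s0²)` is fitted by the moment method on `log s²`: the offset log
variances have known digamma/trigamma moments under a scaled-F sampling
model, and `d0` is recovered by trigamma inversion (Newton iteration).
When the observed spread of log variances does not exceed its sampling
component, `d0 = ∞` and every variance shrinks fully to the prior. The
moderated statistic uses the posterior variance
`(d0·s0² + d·s²)/(d0 + d)` and `d0 + d` degrees of freedom. Setting
`prior_df=0` recovers the ordinary pooled t exactly — both code paths
exist because small panels (28 probes) give the moment fit little to work
with, and the unmoderated test is a legitimate alternative. The
implementation is cross-checked against the Bioconductor reference
implementation (limma) to machine precision in the test suite.

Summary-table conventions: the overall mean is the size-weighted pooled
mean of the group means; **fold change is the ratio of the group means of
log2-normalized abundance** (malignant mean / benign mean). This differs
from the common `2^Δ` convention and is stated prominently: it is the
arithmetic that reproduces the panel's published summary table (group
means 7.0 and 9.3 print as fold change 1.3), and the package exists to
mirror that table's columns. Probe selection is on unadjusted p < α
(default α = 0.05), with the BH FDR reported alongside; BH is the standard
step-up with q clipped at 1 and mapped back to input order.

## PC1 risk signature

The risk score is the projection onto the leading eigenvector of the
covariance matrix of the selected probes: columns centered, not scaled by
default (the score reads as a weighted average of expression in log2
units; correlation-PCA is available as `standardize=True` — the two modes
cannot be adjudicated from summary statistics alone, so both exist and the
covariance mode is the default). The weight vector has unit norm; its sign
is fixed so the score correlates nonnegatively with the per-sample mean of
the selected probes ("higher score = higher overall signature
expression"), resolving the inherent sign ambiguity of eigenvectors; exact
eigen-ties are broken deterministically by making the first nonzero weight
positive. New samples are scored against the *training* centering offsets
— no re-centering — so the score is a legitimate prospective predictor.
Variance explained is the leading eigenvalue over the trace.

## Diagnostic evaluation

* **AUC** is the normalized Mann–Whitney concordance (ties count ½),
  computed from midranks; the confidence interval is DeLong's asymptotic
  variance by default (no CI method is canonical for this statistic; the
  DeLong interval is the field default and a stratified bootstrap with
  2000 resamples is available), clipped to [0, 1]; the p-value is the
  DeLong z-test against AUC = 0.5.
* **Youden threshold**: candidates are midpoints between adjacent distinct
  scores plus ±∞; predicted-positive means score ≥ threshold (the boundary
  had to fall somewhere; ≥ is used consistently); J-ties break toward
  higher specificity, then the larger threshold — in a rule-out/rule-in
  tradeoff at equal J the more specific operating point is preferred.
* **Logistic models** are maximum-likelihood fits with intercept, Wald 95%
  intervals on the odds ratios, an error on rank-deficient designs, and a
  separation flag (raised on optimizer failure, probability collapse, or
  coefficients beyond ±20) instead of silently divergent estimates.
* **IDI** is the change in discrimination slope between two probability
  models, with the paired normal approximation on per-subject probability
  differences (bootstrap optional). It is antisymmetric and exactly zero
  for identical models.
* **Repeated stratified k-fold CV** re-runs the entire discovery procedure
  — probe selection, PC1 fit, orientation and Youden thresholding — inside
  every training fold; held-out scores are pooled into one AUC per
  repetition and held-out predictions (at each fold's training-derived
  threshold) into accuracy/sensitivity/specificity/PPV/NPV. Within
  `repeated_cv` the decision score is the oriented PC1 score itself: a
  logistic link on a single score is strictly monotone, so it cannot
  change the AUC or the threshold ranking, and omitting the per-fold
  logistic refit removes most of the runtime without changing any reported
  metric. Logistic fits are retained where their coefficients are the
  output (discovery reports, the model grid). Folds are stratified —
  plain random splits at n ≈ 31 would regularly produce single-class
  folds; a repetition whose training folds still miss a class is
  reshuffled and counted. Defaults: k = 10, 1000 repetitions
  (configurable; summaries use the mean and the 2.5/97.5 percentile
  interval across repetitions, and the acceptance script uses 200
  repetitions against a 1000-repetition reference mean).

## Multimodal model grid

One logistic model per covariate combination over clinical flags
(high-risk stigmata, worrisome features, gender, jaundice) and the three
signature channels (lncRNA PC1 score, miRNA score, radiomic score —
the latter two consumed as precomputed per-sample covariates; their
derivation is out of scope). The grid runs on the complete-data subset
(rows with all referenced covariates present), whose size is recorded;
models referencing absent columns are skipped with a log entry. Each model
is evaluated at its Youden threshold; AUC-vs-chance p-values are
BH-adjusted across the grid; each model's IDI is computed against the
clinical-only base model (worrisome features + gender + jaundice).
Continuous scores enter the models directly (no binarization; the
binarized alternative would need patient-level data to calibrate and is
not implemented).

## Synthetic data generator

The generator emulates the *structure* of a plasma lncRNA panel study:

* **Counts**: log-normal on the log2 scale, rounded —
  `count = round(2^(baseline + delta·malignant + N(0, sd)))`. The
  log-normal choice (over a negative binomial) makes the log2 analysis
  scale exact and gives every linear score a closed-form binormal AUC,
  `Φ(√k·δ/(σ√2))` for k equal, independent planted probes
  (`expected_signature_auc`), which the test suite uses as an analytic
  oracle. Baselines default to an even spread over 6–13 log2 units, the
  abundance range typical of the panel.
* **Study design defaults**: 21 benign / 30 malignant IPMN cases and 22
  non-diseased controls; 28 endogenous probes; eight malignancy-associated
  probes planted at delta = +1.0 log2 units; within-group SD 1.0 log2
  units. The planted-effect size and SD are free parameters — no per-probe
  dispersions are published for this panel — and 1.0/1.0 was fixed once as
  a realistic moderate effect (per-probe detection power ≈ 0.93 at
  α = 0.05, so discovery is informative but not trivial).
* **Controls**: housekeeping at a stable expected count (default 2000,
  technical CV ≈ 3.5%), zero planted shift; negative controls from a
  truncated normal (mean 15, SD 5 counts), independent of class; positive
  controls a fixed geometric ladder (plumbing only); spike-ins more
  variable than housekeeping, matching why housekeeping genes are the
  scaling choice.
* **Contamination**: a per-sample hemolysis event (default probability
  0.10) jointly raises one absorbance channel above 0.2 and the
  erythrocyte marker counts about 8-fold, so the absorbance rule and the
  marker-based comparison see the same events.
* **Clinical covariates**: binary flags sampled independently given class
  at the cohort's published prevalences (jaundice 5%/27%, main-duct
  involvement 22%/30%, mural nodule 14%/27%, male 38%/63% in
  benign/malignant); high-risk stigmata and worrisome features at
  5%/73% and 48%/54%, chosen so a binary predictor's AUC,
  `(TPR + TNR)/2`, matches the published single-feature AUCs (0.84 and
  0.53). Continuous covariates (cyst size, CA19-9, albumin) follow the
  cohort's group means and spreads.
* **External scores**: class-conditional normals with unit variance and a
  malignant-group mean of `√2·Φ⁻¹(AUC)`, hitting the configured binormal
  AUC (defaults 0.73 miRNA, 0.77 radiomic).

What the generator does **not** emulate: probe-probe correlation beyond
that induced by the class label (real panels share regulatory programs and
technical covariance), correlation between the external score channels and
the lncRNA signature (they are drawn independently, which *overstates*
multimodal fusion gains relative to correlated real channels — simulated
combined models reach higher AUCs than any real cohort should be expected
to), count overdispersion beyond log-normality, batch/lane effects, and
missingness patterns other than the complete-data multimodal subset.
Passing tests therefore demonstrate the correctness and calibration of the
*procedures*, not the clinical performance of any particular panel.

## Problem sizes and numerical choices

Test-suite and acceptance-script simulations use the study-design sizes
above; the heavier checks use 1000-probe null panels for p-value
calibration, 100 generator seeds for planted-probe recovery, n = 2000/2000
for the analytic AUC limit, and 200 cross-validation repetitions against a
1000-repetition reference on the 31-sample multimodal subset. The null
cross-validation check averages over label permutations: a single null
dataset's pooled 10-fold CV AUC has sampling SD ≈ 0.1 at n = 50, so the
chance-level band is asserted on the permutation-averaged mean.

Numerical details: trigamma inversion by Newton iteration (relative
tolerance 1e-10); unit-norm check on signature weights at 1e-9; scaled
housekeeping geometric means equal across samples to 1e-9 relative;
probabilities from logistic fits clipped away from {0, 1} by 1e-12 before
IDI arithmetic; BH uses a stable mergesort so permutation equivariance is
exact.

## Known limitations

* The moderated-t path assumes a two-group design; covariate-adjusted
  linear models, paired designs and count-weighting are out of scope.
* Only the first principal component is extracted; sparse or supervised
  variants are not implemented.
* The DeLong interval is asymptotic and can be anti-conservative at very
  small n; the bootstrap option exists for that case.
* Published summary tables round to one decimal (means) and three decimals
  (p-values); arithmetic recomputed from them can differ from the printed
  derived columns by up to about one print unit, and the tests bound the
  agreement accordingly.
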