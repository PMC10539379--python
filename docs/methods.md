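# Methods

This note documents the models, rules and numerical choices behind
`trdprs`, and what the synthetic-data tests do and do not demonstrate.

## Register phenotyping

**Treatment episodes.** Prescriptions are grouped by subject and full
7-character ATC code and sorted by dispense date. A new episode opens
whenever the gap to the previous dispense of the same drug *exceeds*
`gap_days` (default 120); a gap of exactly 120 days stays within the
episode ("within 120 days" read inclusively). Episode duration is last
minus first dispense date; an episode is *adequate* when the span is
≥ `adequate_days` (default 42, six weeks — long enough for a
therapeutic effect and distinguishable from an immediate switch).
Duplicate (subject, drug, date) rows are collapsed before grouping, so
classification is invariant to record order and duplication. Dates are
integer day offsets from a study epoch throughout; the rules are pure
day arithmetic, so calendar parsing belongs at I/O boundaries only.

**Counting before ECT.** For the narrow definitions, only dispenses
*strictly before* the first ECT date count: a dispense on the ECT day
does not, and an episode spanning the cutoff contributes only its
pre-cutoff dispenses, with adequacy re-evaluated on the truncated
chain — treatment received after ECT cannot justify the referral.
Distinct antidepressants are distinguished at the full ATC-code level
(the finest register-available unit); the prefix and thresholds are
configurable in `PhenotypeParams`.

**Classification.** Broad: TRD iff any ECT event; everyone else is
non-TRD. Narrow_1/narrow_2: TRD iff ECT preceded by ≥ 1 / ≥ 2 distinct
adequate antidepressants. ECT subjects failing a narrow criterion are
*excluded* from that comparison rather than relabelled — an ECT-treated
case can never serve as a control. Non-ECT subjects with more than
`max_adequate_for_control` (= 2) adequate antidepressants are excluded
from the narrow comparisons (they are neither clearly resistant nor
likely responders) but remain non-TRD under the broad comparison.
Narrow controls are additionally required to carry at least one
antidepressant record (adequacy not required); this is the
"had used antidepressants" reading and is configurable
(`control_requires_antidep`). Lithium exposure is detected over the
full record window (configurable), since the sensitivity analysis
targets lithium use generally. These conventions guarantee the nesting
broad ≥ narrow_1 ≥ narrow_2 on case counts for any input.

## Genotype QC

SNP screens run sequentially, each counting only its own removals:
coarse call rate (< 0.95), strict call rate (< 0.98), invariant sites,
Hardy–Weinberg exact p < 1e-6 tested separately in cases and controls
(removal if either fails), case-control call-rate difference > 0.01,
MAF < 0.01. The HWE test is the exact conditional test (enumeration of
heterozygote counts given allele counts, summing probabilities ≤ the
observed configuration's), evaluated in log-space with `gammaln` —
a chi-squared approximation is unreliable at p ≈ 1e-6. Sample screens:
call rate < 0.98; heterozygosity-based inbreeding coefficient
F = 1 − observed/expected heterozygosity (expected from pooled
per-SNP frequencies over the sample's called variants), removing
|F| > 0.20; sex mismatch between reported sex and the sex inferred
from the X-marker heterozygosity rate (< 0.02 male, > 0.20 female,
ambiguous in between → never removed).

**Relatedness.** π̂ (proportion of genome shared identical-by-descent)
is the method-of-moments solution of the IBS-ladder moment equations
(Purcell et al. 2007 style, without small-sample bias corrections):
IBS 0/1/2 counts per pair are computed by indicator-matrix products,
expected per-variant IBS probabilities per IBD state come from sample
allele frequencies, and π̂ = P(IBD=2) + P(IBD=1)/2 after clamping each
state probability to [0, 1]. Expected-count sums are scaled by each
pair's jointly-called fraction — exact under variant-independent
missingness. For each pair with π̂ > 0.2 the member with the lower
call rate is removed (ties keep the earlier subject). Note the
estimator's sampling SD is roughly 0.06 at 400 independent SNPs and
0.025 at 2,000, so thresholding at 0.2 is only meaningful with a few
thousand markers or more; the pipeline default (2,000 SNPs) sits at
the edge of that regime and removes a small noise tail (~0.5% of an
unrelated sample).

**Ancestry.** The top two principal components are computed on a
labelled reference panel (variants standardized by reference
frequencies), study samples are projected through the reference SNP
loadings, and a sample is flagged when PC1 or PC2 lies more than 6
target-population SDs from the target-population mean. Synthetic runs
use a self-contained two-population reference with a configurable
allele-frequency shift in place of a global panel.

## Scoring

Score filters are applied to the *summary statistics* (not target
frequencies), in order: effect-allele frequency outside [0.1, 0.9];
INFO < 0.9; duplicated ids (all copies); A/T and C/G strand-ambiguous
pairs; MHC SNPs, chr6 positions in [28e6, 34e6] inclusive (GRCh37, the
build of the imputation reference). An optional id whitelist covers
HapMap3-style intersection. Survivors are matched to the target by id;
when the effect allele equals the target's second allele, the variant
is scored on 2 − dosage (equivalent to sign-flipping the weight up to
a constant that standardization removes); irreconcilable allele pairs
are dropped. The raw score is the weighted effect-allele dosage sum;
missing dosages are imputed to 2 × effect-allele frequency (the
convention of standard scoring tools on imputed data; an
omit-and-rescale policy is available). Scores are standardized within
the whole scored sample, and zero variance is an error, never a silent
NaN.

## Association battery

Per definition × trait: (1) Welch two-sided t-test on the case-control
mean difference of the standardized score (Student pooled-variance
available; the choice matters little at these group sizes); (2)
logistic regression of status on the score plus the first four PCs
computed within the post-QC analysis sample, reported as OR per SD
with Wald 95% CI and p (profile-likelihood CI available); Newton
iterations to gradient norm < 1e-8, with perfect separation and rank
deficiency raised as named errors identifying the offending direction
or columns. (3) Nagelkerke R² from the full-vs-covariates-only
likelihood comparison, converted to the liability scale with the
threshold-model transformation R²_liab = R²_obs·[K(1−K)]²/(z²·P(1−P)),
K = 0.10 (the assumed population share of MDD cases meeting the
stringent TRD definition), z the normal density at Φ⁻¹(1−K), and P the
per-comparison sample case fraction. The observed-to-liability
convention (applying the threshold transformation directly to
Nagelkerke R², with P the raw case fraction) is one of several in use;
it is implemented behind the named function `liability_r2` so the
choice is auditable and replaceable. (4) Cochran–Armitage trend over
score quartiles with equally spaced scores 1–4, quartile boundaries
from the pooled sample and boundary ties assigned to the lower
quartile. (5) Benjamini–Hochberg step-up FDR applied separately to the
six primary t-test p-values and the six primary regression p-values
(2 traits × 3 definitions); sensitivity rows (added MDD/bipolar score
covariates; lithium-using cases removed) do not enter the adjustment.

## Synthetic-data generator

The generator's defaults are the study conditions: ~4,500 MDD cases in
three cohorts (42/21/37% — ECT-referral, psychotherapy, population),
2,000 independent post-imputation SNPs with frequencies uniform on
[0.15, 0.5], per-SD lithium-response OR 1.12, antidepressant-response
OR 0.98, base TRD rate 0.44 (the broad case fraction). Latent
standardized trait scores are weighted allele counts from the scorable
weight rows; TRD status is Bernoulli with
logit p = logit(base) + log(OR_li)·z_li + log(OR_ad)·z_ad. Treatment
histories realize the labels: every TRD subject gets a first ECT day
(uniform on day 400–1200) and a pre-ECT antidepressant history drawn
from a four-way mix — no antidepressant / records but none adequate
(chains broken by gaps > 120 d) / exactly one adequate / two-plus
adequate — with default mix (5.9%, 10.5%, 22.8%, 60.8%) chosen to
reproduce the observed attrition from the broad to the narrow case
groups (94.2% → 83.6% → 60.8% of ECT cases); 34.5% of controls get
three adequate antidepressants (narrow-excluded), matching the
observed 65.5% narrow-control fraction, and every control has at least
one antidepressant record. 30% of TRD subjects receive lithium
dispenses. Weight tables are salted with five deliberately invalid
SNPs per filter class so every score filter is exercised, and ~20% of
valid rows list the target's second allele as effect allele to
exercise reconciliation. Genotype missingness (default 1%) is injected
only after the latent scores are computed — genotypes are
"imputation-complete" by construction and missingness exists to
exercise QC. X-chromosome markers are not simulated; the per-subject
X-heterozygosity rate is emitted directly for the sex check. All
randomness flows from one seed through named `SeedSequence` child
streams, so studies are bit-identical given the seed and stages can be
regenerated in isolation.

**What the generator does not emulate:** linkage disequilibrium
between SNPs (weights are treated as already LD-rescaled), dosing
quantities, comorbidity or covariate confounding beyond ancestry PCs,
cohort-specific ascertainment differences, and realistic inter-
dispense gap distributions (gaps are uniform 21–60 days within
episodes; the registers' empirical distribution is unpublished, so
defaults are chosen for rule coverage, not realism). Passing tests
therefore demonstrate correctness of the *rules and estimators* under
the design's effect sizes and sample sizes, not robustness to the
messiness of real register or array data.

## Problem sizes and numerics

The test suite and analysis scripts use scaled problem sizes chosen to
keep full runs in minutes on one CPU: the end-to-end pipeline default
is n = 3,000 subjects × 2,000 SNPs (≈ 1 minute); the analysis scripts
run the full 4,500 × 2,000 design; replicate recovery uses 500
replicates at the narrow_1 group sizes; the null-calibration check
pools 2,000 battery replicates at 300/300 per comparison, where the
Wald test's finite-sample size is already within a point of nominal.
PCA and reference projection fix component signs (largest-|loading|
entry positive) so outputs are byte-reproducible. The BH adjustment is
delegated to `statsmodels.multipletests` and cross-checked in the
tests against a direct step-up implementation; the exact HWE test,
Cochran–Armitage trend, π̂ moment estimator, Nagelkerke and liability
conversions are implemented here and tested against exact-rational or
closed-form oracles.

## Known limitations

* π̂ requires a few thousand informative SNPs before the 0.2 threshold
  separates relatives from noise (see above).
* The liability conversion's convention ambiguity (above) means
  absolute R²_liab values should be compared only within a convention.
* The sample-QC F_HET uses pooled allele frequencies, which inflates
  |F| slightly under strong population structure; run the ancestry
  screen first if structure is expected.
* `snp_qc`'s differential-missingness screen at threshold 0.01 is
  calibrated for thousands of subjects; at a few hundred subjects its
  binomial noise floor exceeds the threshold and it removes a
  substantial fraction of clean SNPs.
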