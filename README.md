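# trdprs

Register-based phenotyping of treatment-resistant depression (TRD) and
polygenic-score association analysis, as a tested, reusable Python
pipeline.

## The problem

Whether a patient with major depressive disorder (MDD) responds to
treatment appears to be partly heritable, but treatment-related
phenotypes are hard to define. A stringent operationalization uses
healthcare registers: electroconvulsive therapy (ECT) is a second/third-
line treatment, so MDD cases who received ECT *after* failing adequate
antidepressant trials are very likely treatment resistant. Comparing
polygenic risk scores (PRS) of antidepressant response and of lithium
response between such TRD cases and non-TRD controls asks whether the
genetics of treatment response overlaps the genetics of resistance —
e.g., TRD cases carrying a higher genetic load for lithium sensitivity
would give a genetic rationale for lithium augmentation in TRD.

`trdprs` implements that full analysis chain:

1. **Episodes** (`trdprs.episodes`) — treatment episodes from dated
   dispensations: same drug (full ATC code), consecutive dispenses at
   most 120 days apart; an episode is *adequate* if it spans ≥ 42 days
   (six weeks).
2. **Phenotype** (`trdprs.phenotype`) — three nested case definitions:
   *broad* (any ECT), *narrow_1* (ECT with ≥ 1 adequate antidepressant
   before the first ECT), *narrow_2* (≥ 2 distinct adequate
   antidepressants before first ECT). Controls are non-ECT cases with
   ≤ 2 adequate antidepressants; lithium use (ATC N05AN01) is flagged
   for sensitivity analysis.
3. **Genotype QC + scoring** (`trdprs.genoprs`) — SNP screens (call
   rate, invariance, exact Hardy–Weinberg test in cases and controls,
   differential missingness, MAF), sample screens (call rate, F_HET,
   X-heterozygosity sex check), π̂-based relatedness pruning, reference-
   projection ancestry outliers; then summary-statistics score filters
   (MAF ≥ 0.1, INFO ≥ 0.9, no duplicates / strand-ambiguous / MHC
   SNPs), allele reconciliation, and standardized weighted allele-count
   scores: PRS_i = Σ_j β_j · d_ij, z = (PRS − mean)/SD.
4. **Association** (`trdprs.assoc`) — per definition × trait: Welch
   t-test on the mean score difference; logistic regression of status
   on the score adjusting for 4 PCs (OR per SD, Wald or profile CI);
   Nagelkerke R² converted to the liability scale at population
   proportion K = 0.10 via R²_liab = R²_obs·[K(1−K)]²/(z²·P(1−P));
   Cochran–Armitage quartile trend; Benjamini–Hochberg FDR over the six
   primary tests.
5. **Synthetic data** (`trdprs.synthdata`) — a generator producing a
   complete study (cohorts, prescription chains, ECT dates, genotypes,
   weight tables, latent truth) with the design's statistical
   structure, so the entire pipeline is testable without register or
   genotype access.

## Worked example

The numbered scripts under `analysis/` run the whole study end to end
and write their tables under `results/`:

```bash
python analysis/01_simulate_study.py     # ~4,500 subjects, 2,000 SNPs
python analysis/02_derive_phenotypes.py
python analysis/03_genotype_qc_scores.py
python analysis/04_association_battery.py
python analysis/05_parameter_recovery.py
python analysis/06_figures.py
```

`02_derive_phenotypes.py` prints the case attrition across definitions
(seed 2023):

```
classified 4500 subjects; 2021 with ECT
      broad: 2021 TRD / 2479 non-TRD / 0 excluded
   narrow_1: 1670 TRD / 1624 non-TRD / 1206 excluded (82.6% of ECT cases)
   narrow_2: 1193 TRD / 1624 non-TRD / 1683 excluded (59.0% of ECT cases)
```

i.e. most ECT-treated cases had at least one adequate antidepressant
trial before their first ECT, and the narrow definitions progressively
restrict the case group. `04_association_battery.py` then prints the
six-test battery; with the generator's default effects (per-SD lithium
OR 1.12, antidepressant OR 0.98) the lithium rows are significant and
the antidepressant rows null:

```
definition   trait  n_cases  n_controls  mean_difference   p_ttest  odds_ratio  p_logistic  p_logistic_fdr  r2_liability
     broad lithium     2006        2461           0.1407 2.871e-06       1.156   2.016e-06       1.209e-05      0.007229
     broad antidep     2006        2461          0.02759    0.3593       1.026      0.3879          0.5274     0.0002375
  narrow_1 lithium     1659        1614            0.145 3.909e-05       1.155   4.285e-05       0.0001286      0.007214
  ...
```

The odds ratio column is the increase in the odds of TRD per standard
deviation of the standardized lithium-response PRS, adjusted for the
first four principal components; `r2_liability` is the (small) share
of liability-scale variance the score explains. The quartile trend
confirms a monotone rise in the TRD proportion from the bottom to the
top score quartile (p_trend < 1e-4 under all definitions in this run).

A one-command equivalent is `trdprs run --out results/run --seed 2023`,
and `trdprs simulate/classify/qc/score/assoc` expose the stages
separately.

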