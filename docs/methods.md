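# Methods

## Score construction and grouping

The genetic risk score is unweighted: each panel SNP contributes its
risk-allele dosage (0, 1 or 2) and the score is the plain sum, so a
K-SNP panel yields an integer in [0, 2K]. Weighting by published effect
sizes is deliberately not offered — external GWAS weights transfer poorly
across populations and have been reported to change little in practice for
small panels. Genotype calls are stored as unordered allele pairs, so file
orientation (REF/ALT in VCF, character order in lab CSV exports) never
affects dosage.

Samples with any missing dosage are dropped from the score by default
(`missing_policy="drop"`); mean imputation by 2 × risk-allele frequency is
available (`"impute"`) but off by default because it makes the score
non-integer and shrinks between-group contrasts.

Grouping: low risk is score < cut-off, high risk is score ≥ cut-off. The
default cut-off is the sample median (computed on the analysis sample,
after exclusions); passing `cutoff=6` reproduces the motivating design
exactly. The SD-scaled score uses the sample standard deviation
(n − 1 denominator); a population-SD variant is available via `ddof=0`.

## Quality control

Allele frequencies come from gene counting. The Hardy–Weinberg test is the
plain chi-square goodness-of-fit on the three genotype classes with
expected proportions p², 2pq, q² (frequency estimated from the same
counts), 1 degree of freedom, no continuity correction by default (a
Yates-corrected variant is a keyword switch). Monomorphic SNPs return a
flagged no-test result and fail QC through the frequency rule.

Retention thresholds (all strict inequalities on the retention side):
minor-allele frequency > 0.05, HWE p > 0.05, missingness ≤ 0.05. If no
SNP survives, the pipeline aborts and surfaces the QC report in the
exception.

## Dietary exposures

Habitual intake is the arithmetic mean of three 24-h recalls (samples
with fewer days are excluded; the minimum is configurable). Percent of
total energy intake uses Atwater densities — 9 kcal/g for fat and all fat
subtypes, 4 kcal/g for carbohydrate and protein; alcohol is not modelled.
%TEI is the *ratio of means* (mean grams over mean energy), the usual
convention in nutritional epidemiology; mean-of-daily-ratios is available
as an option since the choice is genuinely open.

The low/high intake split assigns values at or below the median to
**low**; the risk-score split assigns the cut-off value to **high**. The
asymmetry is intentional and tested.

## Regression analyses

All models are OLS with intercept, adjusted for age, sex (women 0, men 1)
and BMI. The transformation rule is fixed, not data-driven: every
biochemical, anthropometric and dietary analysis variable is natural-log
transformed except total fat, carbohydrate and MUFA %TEI. The
Shapiro–Wilk test is computed and reported but never gates the rule;
keeping the rule fixed keeps analyses comparable across cohorts and
replicates. Adjustment covariates enter untransformed: the rule is about
the scales on which effects are estimated and interpreted (outcomes and
exposures), and log-transforming a covariate would change nothing of
interest while complicating interpretation. Blood-pressure triplicates
are averaged first, then transformed.

Association models are fitted twice per outcome: binary high/low group
(primary) and SD-scaled continuous score (secondary); both are always
emitted. When the outcome is logged, `exp(beta)` and its CI are reported
as fold changes.

The interaction screen enters diet as the continuous (transformed) %TEI
by default; the dichotomised variant (`diet_form="binary"`) is a config
switch and is what the stratum summaries visualise. The interaction
p-value is the product-term t-test, which equals the partial-F test for
that single term (asserted in the suite). Stratified follow-up refits the
high-vs-low score model within each intake stratum; strata smaller than a
configurable floor (default 10) or without estimable models are flagged
unstable rather than silently reported. Fat-subtype follow-up (SFA, MUFA,
PUFA) runs only when the total-fat screen for that outcome is significant
at the family-wise α (or under `--force-followup`).

Descriptive tables report raw-scale means ± SD with Student's
equal-variance t-tests (Welch behind a flag) and an uncorrected 2×2
chi-square for sex-by-group composition.

Multiple testing uses Bonferroni: α/7 for the association family
(displayed as 0.007) and α/21 for the interaction family (3 dietary
factors × 7 outcomes, displayed 0.002); raw values are retained so that
m × threshold = α exactly.

The minimum detectable effect for a single additive-coded SNP is

    beta_min = (z_{1−α/2} + z_{power}) · sd / sqrt(n · 2·maf·(1−maf)),

which gives the closed-form MAF ratio
beta_min(0.05)/beta_min(0.5) = sqrt(0.5/0.095) ≈ 2.294 independent of n
and residual SD. Only this ratio is asserted; absolute bounds depend on a
residual SD that is study-specific.

## The simulator

`synthetic_cohort` generates cohorts with the structure the analysis
assumes, with one seeded generator consumed in fixed order (genotypes →
covariates → recalls → traits), so identical configurations reproduce
cohorts bit for bit.

* **Genotypes** — two independent allele draws per SNP (HWE by
  construction) at configurable risk-allele frequencies. Default panel
  frequencies are fixtures in (0.3, 0.5), chosen so the expected score
  sits near the cut-off of 6 and both risk groups are well populated.
* **Covariates** — age uniform 19–24 y, sex Bernoulli(0.5), BMI normal
  (23, 3) kg/m² floored at 15, sex-specific heights; weight is derived
  from BMI and height so the BMI invariant holds exactly.
* **Diet** — latent habitual intake per person (TEI lognormal with mean
  2100 kcal and SD 450; fat normal 31.5 ± 5 %TEI; protein 17 ± 3 %TEI;
  carbohydrate the remainder; all floored at 1 %TEI), times multiplicative
  day noise with CV 0.25 for three recall days, truncated at zero. The
  SFA/MUFA/PUFA split of fat varies between people (means 0.27/0.34/0.24,
  jointly capped at 0.98 of total fat) so subtype exposures correlate with
  total fat without being collinear — at the default means SFA sits near
  8.6 %TEI when total fat is 31.5 %TEI. Grams are back-computed through
  the Atwater factors, so the exposure module recovers the latent
  percentages in expectation.
* **Traits** — TAG, HDL, LDL, SBP and DBP follow the log-linear analysis
  model with configurable intercept, group, diet, interaction, age, sex
  and BMI coefficients and residual SD; intercepts are set so cohort
  means land at healthy young-adult levels. Total cholesterol is
  assembled as HDL + LDL + TAG/5, keeping Friedewald back-derivation
  self-consistent; the TAG:HDL ratio is derived, so its log-scale
  coefficients are differences of the TAG and HDL coefficients.
  Blood-pressure triplicates add 2 mmHg measurement noise around the
  latent value.

The dietary term used in trait generation is the **observed** exposure —
recomputed from the simulated recalls through the same ratio-of-means
path the analysis uses, transformed by the same rule and centred at a
reference value. This makes the generative model identical to the fitted
model: the product-term coefficient is translation-invariant in the
exposure, so interaction recovery is exact and free of measurement-error
attenuation. A mis-specification mode (`continuous_dosage_truth=True`)
instead drives traits from the centred continuous dosage count while the
analysis fits the binary group, for robustness studies; it is off by
default so recovery stays well defined.

`replicate_experiment` derives per-replicate seeds from the master seed
via a `SeedSequence`, runs simulate → QC-free score → exposures → model
per replicate, and reports rejection rate, mean estimate, bias and 95 %
CI coverage, each with its Monte-Carlo standard error.

### What the simulator does and does not emulate

It reproduces the *statistical* structure: HWE genotypes, within-person
recall variation, log-linear traits, a Friedewald-consistent lipid panel.
It does not model linkage disequilibrium between SNPs, population
stratification, recall misreporting bias, alcohol energy, or
food-source/chain-length differences among SFAs. Passing tests therefore
demonstrate that the pipeline's estimators and tests behave correctly
under the assumed model — unbiased interaction estimates, nominal type-I
error and coverage — not that any particular real-world cohort satisfies
those assumptions.

## Numerical choices and problem sizes

* Friedewald LDL uses divisor 5 with all lipids in mg/dl, is considered
  invalid above TAG 400 mg/dl (reader leaves LDL missing there), and a
  negative LDL is returned with a warning rather than dropped — exclusion
  is a QC decision, not an I/O decision.
* Non-positive values under the log rule raise an error naming the sample
  and variable; nothing is silently shifted or clipped.
* Rank-deficient designs raise an error naming the collinear columns.
* CIs use the t distribution on residual degrees of freedom; p-values are
  two-sided.
* Monte-Carlo studies in the test suite and acceptance script use
  n = 190 per cohort and 500 replicates for operating characteristics
  (200–300 for secondary monotonicity/localisation checks), sizes at
  which the Monte-Carlo standard errors are small relative to the
  tolerances asserted.
* Tie handling in score deciles: samples are ordered by (score, id) and
  split into ten equal-as-possible groups, guaranteeing ten rows per
  trait despite integer-score ties.

## Known limitations

* The exposure screen treats one dietary factor at a time; no joint or
  substitution models.
* No weighted or external-GWAS-validated scores; no LD-aware panel
  pruning; no exact (Haldane) HWE test — the chi-square approximation is
  adequate at the cohort sizes targeted and its calibration is verified
  by simulation.
* OLS with homoscedastic errors only; no robust/sandwich or mixed models.
* The Friedewald equation is known to be biased at high TAG even below
  the 400 mg/dl bound; direct LDL measurement, when available in the
  cohort table, bypasses the issue.
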