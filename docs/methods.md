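# Methods

## Study design being modelled

`crcrisk` targets the frequency-matched case-control design: incident CRC
cases and population controls matched on sex, region, and 5-year age band.
Matching makes age, sex and region uninformative as predictors, so every
risk model adjusts instead for a propensity score — the logit-scale
prediction of case status from age (continuous by default, optionally
5-year bands), sex, education, recruiting centre, three genetic-ancestry
components, and the age×sex and centre×sex interactions. The propensity
score enters downstream models as a single continuous covariate; no
weighting or stratification estimators are provided, since the
covariate-adjustment form is the design the package reproduces.

## Scores

**ERS** counts six binary modifiable indicators. The cut-off conventions
are fixed by the study's category definitions: alcohol strictly above
4 SUA/day (men) / 2 SUA/day (women); BMI ≥ 30 kg/m² inclusive; exactly
0 MET h/week of leisure activity; vegetables ≤ 200 g/day inclusive; red
meat strictly above 65 g/day; NSAID/ASA non-use or sporadic use. Smoking
(ever vs never) and family history are derived but excluded from the ERS —
smoking because it is not independently predictive once the other factors
are in the model, family history because it is not modifiable and is
carried as a separate term.

**GRS** is the allele count over the 21-SNP panel. The X-linked SNP
rs5934683 is coded 0/0.5/1; hemizygous males carry genotypes {0,1} which
map to {0, 0.5}, the heterozygote-equivalent code, keeping the X
contribution on the same scale in both sexes. The theoretical unweighted
range for this panel is [0, 41]. Weighted variants multiply the coded
counts by per-SNP log-odds weights, either ln(published OR) from the panel
table or coefficients refitted jointly on a cohort.

**RS** = OR_E^(ERS−ē) · OR_F^FH · OR_G^(GRS−ḡ) with defaults
OR_E = 1.36, OR_F = 2.25, OR_G = 1.07, ē = 3, ḡ = 22, so the reference
profile has RS = 1 exactly. Two published-figure caveats are deliberate:
(i) the published worked example for (ERS = 6, FH = 1, GRS = 28) prints
7.25, but the formula with the printed rounded coefficients evaluates to
≈ 8.49 — presumably the original used unrounded fitted coefficients. The
package evaluates the formula as written; `RiskScoreParams` accepts
unrounded coefficients (e.g. from `fit_risk_model`) when that behaviour is
wanted. (ii) ḡ = 22 matches the reported control mean allele count, yet
the panel's tabulated risk-allele frequencies imply a mean near 18
(frequencies likely from discovery-GWAS populations). Both references are
configurable; neither is asserted as ground truth, and
`SnpPanel.with_frequencies` supports recalibrating the panel toward a
target mean.

## Synthetic cohort generator

The generator is the package's stand-in for the raw study data and defines
the conditions under which everything is tested.

* **Genotypes**: Hardy-Weinberg, Binomial(2, p) per autosomal SNP at the
  panel frequencies; females Binomial(2, p) and males Binomial(1, p) for
  the X SNP. No linkage disequilibrium, no population structure (the three
  ancestry components are emitted as standard normals, independent of
  everything).
* **Risk factors**: independent Bernoulli draws at the published control
  prevalences (alcohol 15.56%, obesity 6.85%, inactivity 38.52%, low
  vegetables 69.17%, high red meat 40.93%, NSAID non-use 27.30%; family
  history 12.14%; smoking 56.45%). Raw continuous variables (SUA/day,
  BMI, MET h/week, g/day intakes) are drawn uniformly within the risk or
  non-risk side of each cut-off so dichotomisation round-trips exactly.
* **Outcome**: P(case) = expit(b₀ + ln 1.36·ERS + ln 2.25·FH +
  ln 1.07·GRS). The baseline logit defaults to −3.0, chosen once to give a
  source-population case rate near 25% so a 1336/2744 study is drawable
  from a modest pool; because case-control sampling only shifts the
  intercept, the slope calibration is unaffected by this choice. Age, sex
  and region have no direct effect by default — they act only through
  matching, mirroring a design where they are matching variables.
* **Matching**: controls are sampled without replacement within
  sex × region × 5-year-band strata, quotas proportional to stratum case
  counts (largest-remainder rounding, minimum one control per case
  stratum, shortfalls redistributed to strata with spare controls); a case
  stratum with no eligible controls is an explicit error naming the
  stratum. The simulation pool doubles (up to 9 times) if sparse strata
  cannot be served. Leftover controls are discarded.
* **Missingness**: optional, missing-completely-at-random per variable.
  Masking a raw variable also masks its derived indicator and the ERS for
  those rows, so "cells changed by imputation = cells missing" holds
  exactly. Case status, age, sex and region can never be masked.

What the generator does **not** emulate: factor correlations (none are
published; factors are independent), recall/measurement error,
non-random missingness, age- or sex-dependent factor prevalences, LD, and
any direct age effect on risk (configurable). Consequently, passing tests
demonstrate the pipeline's statistical correctness under the published
marginal structure — not robustness to the confounding patterns of real
interview data.

## Imputation

Continuous variables: the expected value from an ordinary least-squares
regression on age, sex and case status fitted to complete cases (predictor
set configurable); categorical/binary variables: the modal category.
Imputation is deterministic given the cohort, never alters observed cells,
and re-derives indicator columns from imputed raw values. The choice of
OLS with that predictor set, and of a linear rather than logistic model
for binaries, is a package decision — only the expected-value-from-
complete-cases principle is inherited from the study description.

## Evaluation

* Plain AUROC is the Mann-Whitney rank statistic (ties worth ½).
* The stratified AUROC splits subjects into propensity quintiles (sample
  quantiles over the pooled cohort; a value equal to a boundary falls in
  the lower stratum) and averages stratum AUROCs with weights proportional
  to stratum case counts. A stratum with no cases gets weight zero with a
  logged warning; a stratum with cases but no controls is an error. With
  one stratum the statistic reduces exactly to the pooled AUROC.
* Cross-validation: 5 folds stratified by case status; the model is refit
  on each training set and the held-out linear predictors are pooled
  before stratification. Confidence intervals are percentile bootstrap
  over subject resamples (default 200), the full CV re-run per resample
  with re-randomised folds; resamples that become degenerate are skipped,
  and the interval is refused if fewer than 80% survive.
* The cumulative-AUROC curve evaluates every model on the same folds
  (same seed), so the comparison between nested models is paired.
* Wald 95% intervals throughout; crude odds ratios use the Woolf log-OR
  standard error and reject zero cells rather than apply continuity
  corrections.
* Screening performance treats RS ≥ cutoff as test-positive; PLR/NLR
  denominators of zero yield flagged infinities.

## Population projection

Projected cumulative risk is CR(age) × RS, capped at 100 per 100 with a
flag. Multiplying cumulative risks (rather than hazards) by an odds ratio
follows the source procedure and is a first-order approximation valid
while CR × RS is small; the cap marks where it has clearly broken down. A
hazard-scale alternative was considered and deliberately not shipped — the
rest of the pipeline never consumes it, and a single documented convention
was preferred over an untested second path.

The risk-advancement period inverts the monotone piecewise-linear CR curve
to find the age at which RS × CR(a) equals the reference CR; flat segments
resolve to the earliest age. On an exponential curve CR = c·e^{ka} the
advancement is ln(RS)/k exactly, which the tests use as a closed-form
oracle.

PPV/NPV use Bayes' theorem with the prior for an age range [a, b) taken as
CR(b) − CR(a), the unconditional cumulative risk accrued over the range
(survival to the range start is ignored — a documented approximation; a
decade-conditional prior would divide by the probability of reaching age a
free of disease, a refinement the available tables do not support).

The packaged incidence table is a synthetic fixture shaped like Spanish
registry CRC curves (near-zero before 40, exponential rise from 50, male
lifetime risk 10 per 100, female 5); it is not extracted from any registry
publication, and all projection functions accept any user-supplied
(sex, age, cumulative-risk) table.

## Problem sizes

The test suite runs replicate studies at reduced size (150–400 cases) for
coverage and optimism properties, one full-size 1336/2744 cohort for
recovery and matching checks, and a 3000/6000 cohort for the
discrimination check; the acceptance script uses 20 replicates at
1336/2744 for effect-size recovery and one 10,000/20,000 cohort for the
cross-validated AUROC. These sizes were chosen to make Monte-Carlo error
comfortably smaller than the tolerances being checked.

## Known limitations

* The model applies to asymptomatic average-risk adults; high-risk
  syndromes and symptomatic subjects are out of scope.
* The generator's independence assumptions mean gene–environment and
  factor–factor correlation structure is untested.
* Odds ratios are used as relative-risk multipliers on cumulative
  incidence, an approximation that overstates absolute risk when
  outcomes are common or RS is large.
* The 21-SNP panel is small by current standards; the machinery accepts
  larger panels, but the packaged calibration reflects this panel only.
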