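# crcrisk

Risk stratification for colorectal cancer (CRC) from environmental and
genetic factors, built for epidemiologists exploring risk-based screening
policy with case-control data.

Population CRC screening is triggered by age alone. `crcrisk` implements a
complete pipeline for asking whether modifiable lifestyle factors, family
history, and a panel of common susceptibility SNPs can usefully stratify
that "average-risk" population: score construction, propensity-adjusted
effect estimation, cross-validated discrimination, and projection of
relative risks onto registry cumulative incidence.

## The model

Each subject is summarised by three quantities:

* **ERS** (environmental risk score): the count, 0–6, of binary modifiable
  risk indicators — high alcohol intake (>4 standard units/day for men,
  >2 for women), obesity (BMI ≥ 30 kg/m²), no leisure-time physical
  activity (0 MET h/week), low vegetable intake (≤ 200 g/day), high
  red-meat intake (> 65 g/day), and NSAID/ASA non-use.
* **GRS** (genetic risk score): the count of risk alleles over a 21-SNP
  susceptibility panel; the single X-linked SNP (rs5934683) is coded
  0/0.5/1 so both sexes contribute on the same scale.
* **FH**: any first/second/third-degree family history of CRC.

Because controls are frequency-matched to cases on age, sex and region,
those variables cannot act as predictors; all models instead carry a
**propensity score** — the logit-scale prediction of case status from age,
sex, education, centre, three genetic-ancestry components and the
age×sex / centre×sex interactions — as one continuous adjustment covariate.

The multivariate risk model is a propensity-adjusted logistic regression;
its fitted odds ratios define a multiplicative relative **risk score**

```
RS = OR_E^(ERS−3) · OR_F^FH · OR_G^(GRS−22)
   = 1.36^(ERS−3) · 2.25^FH · 1.07^(GRS−22)
```

normalised so the population-average profile (ERS = 3, FH = 0, GRS = 22)
has RS = 1. Discrimination is assessed with an AUROC computed within
propensity-score quintiles and averaged with case-count weights, under
5-fold cross-validation with bootstrap confidence intervals. Multiplying
registry cumulative incidence by RS yields absolute-risk curves,
risk-advancement periods, and — via Bayes' theorem — PPV/NPV of RS
cut-offs per age decade.

Since the original interview/genotype records are not public, the package
includes a first-class synthetic-cohort generator
(`crcrisk.synthetic`) that reproduces the study's statistical structure:
Hardy-Weinberg genotypes at the panel's risk-allele frequencies, binary
factors at the published control prevalences, a logistic outcome model
with the published effect sizes, and frequency matching on sex × region ×
5-year age band.

## Worked example

```python
import crcrisk as cr

cohort = cr.generate_cohort(cr.GeneratorConfig.default(), seed=42)
cohort = cr.attach_propensity(cohort, cr.fit_propensity(cohort))

fit = cr.fit_risk_model(cohort)  # ERS + family history + GRS + propensity
print(fit.table.loc[["ers", "family_history", "grs"],
                    ["or_", "ci_low", "ci_high"]].round(3))

auroc = cr.cv_auroc(cohort, cr.evaluate.FACTOR_MODEL_TERMS, n_boot=200, seed=0)
print(f"5-fold CV stratified AUROC: {auroc.estimate:.3f} "
      f"(95% CI {auroc.ci_low:.3f}-{auroc.ci_high:.3f})")

rs = cr.compute_rs(ers=5, fh=1, grs=26)
print(f"RS for ERS=5, FH=1, GRS=26: {rs:.2f}")

inc = cr.synthetic_incidence()
adv = cr.risk_advancement_age(inc, rs=2.0, reference_age=50, sex="male")
print(f"risk advancement at age 50 for RS=2 (men): {adv:.1f} years")

ppv, npv = cr.ppv_npv(sens=41.62, spec=84.66, prior=0.03)
print(f"PPV at RS>=2 with a 3% prior: {ppv:.3f}; NPV: {npv:.3f}")
```

prints

```
                  or_  ci_low  ci_high
ers             1.308   1.226    1.396
family_history  2.081   1.726    2.511
grs             1.080   1.054    1.106
5-fold CV stratified AUROC: 0.618 (95% CI 0.600-0.641)
RS for ERS=5, FH=1, GRS=26: 5.46
risk advancement at age 50 for RS=2 (men): 4.8 years
PPV at RS>=2 with a 3% prior: 0.077; NPV: 0.979
```

The fitted odds ratios recover the generator's true effects (1.36 per
factor, 2.25 for family history, 1.07 per allele) within sampling error on
a single 1336-case / 2744-control cohort; the cross-validated AUROC near
0.62 shows the modest but real discrimination such a model achieves. A
subject with five risk factors, family history, and 26 risk alleles
carries about 5.5× the average population risk; a man with double the
average risk reaches the average 50-year-old's cumulative risk about five
years early, and at an RS ≥ 2 cut-off a 3% background risk updates to a
7.7% post-test probability.

The same pipeline is scriptable from the shell:

```
crcrisk simulate --out sim/
crcrisk prepare --in sim/cohort.tsv --out prepared.tsv
crcrisk propensity --in prepared.tsv --out with_ps.tsv
crcrisk score --in with_ps.tsv --panel sim/panel.tsv --out scored.tsv
crcrisk fit --in scored.tsv
crcrisk evaluate --in scored.tsv --out perf.tsv
crcrisk project --rs 1,2,4 --out proj/
crcrisk ppv --perf perf.tsv --decades 40-49,50-59,60-69,70-79 --out ppv.csv
```

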