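# twinmetab

Twin-design heritability analysis of urinary metabolomics panels in
children: QC-driven preprocessing, family-clustered sex/age association
scans with false-discovery-rate control, and classical-twin-design
variance decomposition by full-information maximum likelihood — exercised
end to end on synthetic twin cohorts with known ground truth.

## The problem

Urinary metabolite levels in children vary with sex and age and aggregate
in families. Monozygotic (MZ) twins share essentially all segregating
genetic variants, dizygotic (DZ) twins on average half, so the contrast
between MZ and DZ within-pair correlations separates genetic from
environmental variance. The package implements the full analysis chain
such a study needs:

1. **Preprocessing** — sample exclusions (insufficient urine, not
   first-morning, freeze delay > 2 h, second multiple pairs, cross-cohort
   duplicates); metabolite filters (item missingness > 10%, pooled-QC
   relative standard deviation RSD<sub>qc</sub> ≥ 15%); imputation of
   left-censored values at half the detection limit; division by sample
   creatinine (urine dilution); rank-based inverse normal transformation
   (Blom offset) per metabolite within cohort.
2. **Association** — per metabolite, a linear mixed model
   `y = Xβ + u_family + ε` with a family random intercept fit by direct
   maximum likelihood, Wald z-tests for sex and age, eight
   sensitivity/stratified analyses (age continuous or dichotomized at 10
   years; sex- and age-stratified scans), Benjamini–Hochberg step-up FDR
   at q ≤ 0.05 per analysis, and discovery–replication concordance.
3. **Twin modelling** — per metabolite, a saturated two-group model fit to
   the raw data by full-information maximum likelihood (each family
   contributes the multivariate-normal density of its observed
   sub-vector, so incomplete pairs are retained); likelihood-ratio
   selection of the sex/age mean covariates; ML twin correlations
   r<sub>MZ</sub>, r<sub>DZ</sub>; the classical rule **ADE if
   r<sub>MZ</sub> > 2·r<sub>DZ</sub>, else ACE**; unconstrained variance
   components with expected covariances

   |      | MZ pairs  | DZ pairs        |
   |------|-----------|-----------------|
   | ADE  | A + D     | A/2 + D/4       |
   | ACE  | A + C     | A/2 + C         |

   negative estimates allowed; broad-sense h² = (A+D)/V under ADE,
   narrow-sense h² = A/V under ACE; profile-likelihood confidence
   intervals for the standardized shares.
4. **Reporting** — reliability banding of MZ correlations (excellent
   ≥ 0.75, good 0.60–0.74, moderate 0.40–0.59, indeterminate < 0.40) and
   per-platform summaries (amines, organic acids, steroid hormones).
5. **Synthetic cohorts** — a generator producing twin families with known
   (A, C, D, E) structure, sex/age mean effects, creatinine dilution,
   LOD censoring, missingness and pooled-QC injections, so every stage is
   testable against ground truth without access-controlled data.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts and write their tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_association.py
python analysis/04_twinfit.py
python analysis/05_report.py
```

Step 02 reproduces the attrition arithmetic on the deterministic fixture
rosters:

```
discovery: 1362 collected -> 1300 analyzed {'late_freeze': 25, 'second_multiple': 22, 'not_first_morning': 13, 'insufficient_urine': 2}
replication: 186 collected -> 179 analyzed {'not_first_morning': 3, 'late_freeze': 3, 'cross_cohort_duplicate': 1}
metabolite QC: 100 assayed -> 86 retained {'amine': 56, 'organic_acid': 20, 'steroid': 10}
```

Steps 04–05 print the variance-decomposition audit against the generator's
truth, e.g.:

```
fit 86 metabolites: 54 ADE, 32 ACE (ground truth 72 ADE regimes; rule agreement 74%)
r_MZ recovery: corr 0.969, mean |error| 0.025
h2 recovery:  mean |error| 0.073
h2 profile CI covers truth for 93% of metabolites
moderate-or-better reliability: 87.2% of 86 metabolites
  amine: r_MZ mean 0.58 (0.36-0.75); broad h2 0.58 (0.36-0.75, n=36); narrow h2 0.43 (0.01-0.72, n=20)
```

The 74% model-rule agreement is not a defect: with only 114 complete DZ
pairs the sampling noise of r<sub>DZ</sub> flips the r<sub>MZ</sub> >
2·r<sub>DZ</sub> decision for metabolites near the boundary — the same
power limitation the classical twin literature documents for D and C
components.

A CLI mirrors the stages for ad-hoc use:
`twinmetab {simulate,preprocess,associate,twinfit,report,run-all}`.

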