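# Methods

## The classical twin design

Phenotypic variance V of a metabolite is decomposed into additive genetic
(A), dominance genetic (D), common/shared environmental (C) and unique
environmental (E) components. MZ co-twins correlate 1 on A and D and DZ
co-twins 0.5 and 0.25 respectively (0.25 is the probability that two
full sibs share both parental alleles identically by descent); C
correlates 1 in both, E in neither. The implied within-pair covariances
are A + D (or A + C) for MZ and A/2 + D/4 (or A/2 + C) for DZ. A, C, D
and E cannot be estimated jointly from two zygosity groups (four
identifiable moments), so one of ADE or ACE is fitted, chosen by the
standard correlation heuristic: ADE iff r_MZ > 2·r_DZ, ties to ACE since
the rule uses a strict inequality. Both three-component models are
exactly identified, which yields the closed-form moment solutions

    ADE: A = 4 cov_DZ − cov_MZ,  D = 2 cov_MZ − 4 cov_DZ,  E = V − cov_MZ
    ACE: A = 2 (cov_MZ − cov_DZ),  C = 2 cov_DZ − cov_MZ,  E = V − cov_MZ

used as independent oracles for the FIML fits: on complete, moment-matched
data the likelihood optimum must equal these to numerical precision, and
the ADE broad-sense h² = (A+D)/V must equal the fitted r_MZ.

## Full-information (raw-data) maximum likelihood

Every family contributes the multivariate-normal log-density of the
sub-vector it actually observed: complete pairs a bivariate density with
means tied across birth order and zygosity and covariance
[[σ², cov_z], [cov_z, σ²]] for zygosity z, incomplete pairs the univariate
marginal. Singletons therefore inform the mean and variance but not the
covariances, and no family is list-deleted; this is valid under MCAR/MAR
missingness.

The saturated model estimates (mean-model coefficients, σ², cov_MZ,
cov_DZ). It is parameterized as (β, log σ², atanh-scaled correlations) so
every proposal is a feasible covariance. Covariate selection compares the
full sex + age mean model against each reduced model by likelihood-ratio
test (χ², df = number of removed coefficients); a covariate is kept iff
its removal is rejected at α = 0.05 (an AIC mode is available). Wald
z-tests are not used here because the saturated fit's natural reporting
unit is the model comparison.

The ADE/ACE models are parameterized directly in the raw components
(A, D|C, E) as unconstrained reals, so negative component estimates are
allowed — with r_MZ > 4·r_DZ the additive component of an ADE fit is
legitimately negative, which is why broad-sense h² rather than separate A
and D shares is the quantity to report. Proposals implying a non-positive
total variance or |cov| ≥ V return a large penalty rather than −∞ to keep
quasi-Newton search stable; the optimizer is L-BFGS-B with a Nelder–Mead
polish and up to three jittered restarts, with starting values from the
closed-form moment solutions.

Confidence intervals for standardized shares (a², c²/d², e², h²) are
profile-likelihood intervals: the share is fixed, the remaining free
parameters (mean coefficients, log V, and the complementary share or the
A/D split under a broad-h² profile) are re-optimized, and the bound is
where twice the log-likelihood drop equals the χ²₁ quantile, located by
outward stepping plus Brent root-finding inside a [−1, 2] window; a bound
pushed outside the window is reported open-ended with a warning.

## Family-clustered association model

Sex/age effects are estimated per metabolite from
y = Xβ + u_family + ε with u ~ N(0, τ²), ε ~ N(0, σ²), fit by direct
maximum likelihood: the likelihood is concentrated over the single
variance ratio ψ = τ²/σ² ≥ 0 (β by GLS and σ² in closed form at each ψ),
leaving a one-dimensional bounded optimization. ML rather than REML is
used; at n ≈ 1300 the difference is immaterial, and ML keeps the
likelihood comparable across mean models. Wald z-tests give the per-term
p-values. With clusters all of size one, ψ is unidentified and the fit
reduces to OLS exactly.

"Family and zygosity" clustering is implemented as the family random
intercept alone: zygosity has two levels, and a two-level "random effect"
is degenerate — the family intercept is what corrects the clustering. A
consequence measured during validation: when the within-family
correlation differs strongly by zygosity (A-driven clustering), the
single-ICC model's Wald p-values are mildly anticonservative in the far
tail (null p < 0.001 occurring at about twice nominal; fraction below
0.05 about 0.06). Under shared-environment clustering (equal ICC) the
p-values are exactly calibrated. The FDR-control validation therefore
simulates the model-faithful (equal-ICC) null; the zygosity-ICC
robustness gap is a known limitation of the association stage, not of
the twin models, which estimate zygosity-specific covariances by
construction.

Eight analyses are run (sex + age with age continuous or dichotomized at
10 years — the cohort median age, boundary to the older group; age-only
within sex strata, both codings; sex-only within the younger/older
strata), each corrected separately by Benjamini–Hochberg step-up at
q ≤ 0.05. The correction's hypothesis count m may exceed the number of
tests run, as when a replication panel retained fewer metabolites; the
per-analysis replication counts (79, 76, 73, 67, 63, 51, 11, 13) ship as
configuration defaults alongside the discovery panel's 86. A discovery
hit replicates iff it is significant in both cohorts with the same beta
sign.

## Preprocessing

Order: sample exclusions → metabolite filters → LOD imputation →
creatinine normalization → inverse normal transform. Exclusions follow
the listed order (insufficient urine, not first-morning, freeze delay
> 2 h, second multiple pair, cross-cohort duplicate) so reason attribution
is deterministic; a missing flag passes with a logged warning. The
missing-rate filter is strict (> 10%), the RSD_qc filter inclusive
(≥ 15%), RSD_qc = 100·sd/mean over pooled-QC injections with an undefined
(zero-mean) RSD treated as failure. Censored entries become lod/2, or
half the lowest observed level when the limit is unknown. Creatinine
units are arbitrary but must be consistent; division cancels them and the
INT removes all remaining scale. The INT uses average ranks for ties and
the Blom offset c = 3/8, mapping rank r to Φ⁻¹((r − c)/(n − 2c + 1)) —
the dominant convention in genetic epidemiology; the offset is
configurable because downstream results are insensitive to it (any
strictly monotone transform of a metabolite yields an identical INT
vector, which is itself a test). The transform is computed per metabolite
within cohort, since the cohorts are analyzed separately. Whether the
missing-rate filter preceded QC corrections, and whether creatinine
normalization preceded the missing-rate computation, are not documented
for the original assay; here missingness is computed on the raw matrix
and creatinine division follows imputation.

## The synthetic-data generator

The generator emulates the discovery cohort's composition by default:
531 complete MZ pairs + 6 MZ singletons, 114 complete DZ pairs + 4 DZ
singletons (1300 children), ages uniform on 5.7–12.9 years shared within
pair, 48.2% girls, MZ pairs same-sex, DZ twins sexed independently
(≈ 50% opposite-sex; no sex-limitation structure is modelled, so the
composition is exposed as a parameter rather than fixed). Latent
metabolite values are unit-variance sums of A/C/D/E components with the
twin correlations above plus linear sex and age mean effects. The raw
scale is exp(0.5·latent) times a lognormal(0, 0.5) creatinine draw —
deliberately a monotone transform, because the INT must make it
irrelevant. Left-censoring takes the per-metabolite LOD quantile of the
raw values; item missingness is MCAR (FIML is valid under MCAR/MAR and
no mechanism is documented for the real assay); pooled-QC injections are
drawn around the pooled mean at a controllable CV (default 8%, safely
inside the 15% filter), one per 10 samples. Everything masked is recorded
in a GroundTruth object first, so masking round-trips exactly. A run is
keyed by one integer seed through a single numpy Generator; identical
seeds give bit-identical cohorts.

When no variance structure is supplied, metabolites draw from an 80/20
mixture of ADE- and ACE-regime structures with r_MZ uniform on 0.4–0.75
and r_DZ placed inside the regime's feasible band, echoing the reported
preponderance of non-additive genetic signal in urinary panels (69 of 86
metabolites ADE-regime in the motivating study).

What the generator does **not** emulate: batch/drift structure beyond QC
dispersion, assortative mating, sex-limitation or age-moderation of the
variance components, longitudinal sampling, and real metabolite
abundance distributions. Passing tests therefore certify the estimators
under the stated model, not robustness to those features of real data.

The deterministic fixtures (`make_paper_fixture_roster`,
`make_paper_fixture_panel`, `make_paper_fixture_correlations`) are
synthetic stand-ins built to carry exactly the published worked-example
tallies — 1362 → 1300 children with exclusion counts 2/13/25/22,
186 → 179, panel attrition 66/21/13 → 56/20/10, and the per-band
reliability counts (5 excellent, 11 good, 62 moderate, 8 indeterminate of
86, i.e. 90.7% moderate-or-better) — so the bookkeeping stages can be
checked against exact expected numbers.

## Numerical and validation choices

- Saturated and component fits converge at ~1e-8 relative log-likelihood;
  closed-form equivalence holds to better than 1e-6 in practice and is
  asserted at 1e-4.
- The reliability band edges printed as 0.60–0.74 / 0.40–0.59 are
  two-decimal renderings; they are implemented as half-open intervals
  [0.60, 0.75) and [0.40, 0.60) so every real correlation gets exactly one
  band. Correlations below 0.40 are labelled *indeterminate*, not "low":
  a low MZ correlation does not imply low reliability.
- D/C component significance is deliberately not tested (the DZ sample is
  too small for useful power); broad-sense h² is the reported quantity
  under ADE.
- Calibration studies: covariate-LRT type-I error and the scan's Wald
  type-I error sit at nominal 5% within Monte-Carlo error (the Wald study
  is also run at 1000 replicates in the test suite, where the 200-replicate
  Monte-Carlo error would be of the same order as the tolerance band
  itself); mean false-discovery proportion of the null 86-metabolite scan
  is controlled at q = 0.05 under the model-faithful null; ACE share
  recovery at the study's sample sizes is unbiased to < 0.01 with a²
  profile-CI coverage ≈ 0.95.
- Problem sizes in the replicate studies (200 replicates at 531/114
  pairs; 20-metabolite oracle panels) were chosen to pin Monte-Carlo error
  well below the assertion tolerances while keeping a full validation run
  in the minutes range on one CPU.

## Known limitations

- The association stage assumes one family ICC across zygosity (see
  above); the twin stage does not share this limitation.
- Profile CI search is windowed to shares in [−1, 2]; pathological fits
  report open-ended bounds rather than extrapolating.
- The exactly-duplicated-cluster limit of the LMM has an unbounded
  likelihood; estimates there depend on the parameterization path and the
  implementation is only guaranteed just off that degenerate point.
- No batch-drift correction is implemented; inputs are assumed already
  drift-corrected upstream (as the QC-corrected relative response ratios
  of the motivating assay are).
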