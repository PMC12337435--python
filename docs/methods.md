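# Methods

## Statistical model

### Lifetime phenotypes

Each disorder is a binary lifetime phenotype assembled from wave-level
assessments: case if the case definition is fulfilled at any wave, control if
it is fulfilled at no non-missing wave, missing only when every wave is
missing. A participant who is a case at one wave and a control at another is
a lifetime case. Composite phenotypes (e.g. an any-of aggregate of several
autoimmune conditions) follow the same rule over their components, and a
control call does not require complete component data. The analysis age is
the age at the first wave fulfilling the definition for cases and the last
age with relevant data for controls, so that dropout does not silently
shorten control follow-up. Sensitivity-analysis exclusions remove
participants who are lifetime cases of a designated confusable condition
from the *target* phenotype's case and control pools (status set to missing)
while leaving their data for all other phenotypes untouched.

### Prevalence estimation

For an outcome disorder and an exposure "has ≥ 1 affected relative of degree
R for the co-disorder", we fit a logistic regression of lifetime status on

    intercept, exposure, age, age², sex, n(relatives of degree R with data)

The age² term absorbs non-linear prevalence trends with age; the
relative-count covariate addresses the fact that only participants with
relatives in the dataset can be exposed, and that such participants may
differ from the cohort at large. Rows with a missing outcome, age or sex are
dropped listwise per model and the per-model n is logged and reported.

Prevalences are *average adjusted predictions* (marginal standardization):
the mean of fitted probabilities at observed covariates, over the full
sample (general-population prevalence K₀) and over the exposed subgroup
(K₁). By the logistic score equations both equal the corresponding raw
prevalences exactly; the model's contribution is the covariate-adjusted
standard error. The default is this subgroup-observed average; a
counterfactual mode (set the exposure column to 1 for every row before
averaging) is available behind a flag, because the marginal-standardization
wording admits both readings and the two differ in finite samples.

Families contribute correlated observations, so coefficient covariance uses
the CR0 cluster sandwich with families (connected pedigree components) as
clusters: bread = inverse observed information, meat = Σ_g s_g s_gᵀ with s_g
the score sum of family g. AAP standard errors follow by the delta method,
se = √(ḡᵀ V ḡ) with ḡ the mean of p(1−p)x over the target group. With every
cluster a singleton this reduces exactly to HC0 (verified against
statsmodels in the tests).

### Recurrence risk ratio

λ_R = K₁/K₀ on the plain ratio scale. Its delta-method variance treats
numerator and denominator as independent,

    Var(λ) = Var(K₁)/K₀² + K₁²·Var(K₀)/K₀⁴ ,

and inference is one-sided (H₀: λ = 1, H₁: λ > 1) with only the 95% lower
bound λ − z₀.₉₅·SE reported — the upper bound of a one-sided ratio CI is
infinite and uninformative. A log-scale bound is available behind a flag for
small samples where the ratio-scale bound can cross zero. When a model has
no exposed individuals or no exposed cases the λ row is emitted as missing
with a warning rather than failing the study run.

The independence assumption is deliberately conservative: the exposed are
part of the general population, so K₁ and K₀ are positively correlated and
the stated SE overstates the sampling variation. The acceptance suite
measures the consequence directly — under a global-null simulation the
one-sided test rejects at the 5% level in well under 5% of replicates, and
the delta SE exceeds a cluster-bootstrap SD. The discrepancy grows with the
exposed fraction (it is mild when the co-disorder is rare or relatives are
few, which is the regime of the bootstrap comparison fixture: trio families
with 5% prevalences, ~7% exposed). This conservatism costs power but does
not bias λ itself.

### Familial correlation

Under the liability-threshold model a trait is the indicator that a standard
normal liability exceeds t = Φ⁻¹(1−K). For a proband's trait A and a
relative's trait B the pair of liabilities is bivariate normal with
correlation a_R·r_f, where a_R is the coefficient of relationship (0.5 /
0.25 for first / second degree) and r_f is the cross-trait familial
covariance on the standardized liability scale — equivalently the liability
correlation attributable to familial factors, genetic and shared
environmental combined (a family design cannot separate the two). The
model-implied prevalence among exposed individuals,

    K_pred(r_f) = P(X > t_A, Y > t_B; ρ = a_R·r_f) / K_B ,

is strictly increasing in r_f, so r_f is identified by bracketed root
finding (Brent, tolerance 1e−8 on r_f) from the observed exposed-group
prevalence. A Reich-type threshold-shift approximation

    t* = (t_A − a_R r_f i_B) / √(1 − a_R²r_f²·i_B(i_B − t_B)),  i_B = φ(t_B)/K_B

is retained for comparability with the older literature; exact and
approximate modes agree within 0.02 predicted prevalence for K ∈ [0.05,
0.4], |r_f| ≤ 0.5 (asserted in the tests). The exact mode is the default
because it remains accurate at high prevalences (~40%, e.g. hypertension).

One r_f is estimated per unordered phenotype pair from up to four
components: {first, second degree} × {A given relative-B, B given
relative-A}. Per component, the SE propagates the exposed-prevalence SE
through the solver by central finite differences (step 1e−4, shrunk near the
boundary). The combined estimate is the inverse-variance-weighted mean of
the solvable components. Because all four components are estimated from the
same families they are positively correlated, so the SE of that weighted
mean is computed from per-family influence functions: each AAP has the
asymptotically linear representation Σ_g IF_g with IF_g = ḡᵀA⁻¹s_g +
Σ_{i∈g∩S}(p_i − K̂)/|S|, the component influences are scaled by dr/dK, and
Var(r̄) = wᵀΣw/(Σw)² with Σ the cross-component influence covariance. A
naive 1/Σw variance would understate the uncertainty whenever components
share data; with identical components the influence-based SE correctly
equals the single-component SE (asserted in the tests). Per-component
estimates and SEs are always emitted so any alternative combination can be
recomputed downstream. Unsolvable components (observed prevalence outside
the attainable range) are dropped with a warning; if none remain the pair's
r_f is reported missing.

Inference on r_f is one-sided (H₀: r_f = 0, H₁: r_f > 0) with the 95% lower
bound reported, mirroring λ.

### Multiple testing

All tests of a study grid — two λ tests per ordered (focal, disease) pair
plus one r_f per unordered pair; 70 + 35 = 105 for a 5 × 7 design — form a
single Benjamini–Hochberg family at q = 0.05. Tests that could not be
computed carry missing p-values and do not count toward the family size m
(a test never performed is not a test). A per-statistic-type family option
exists behind a flag.

## Numerical choices

- **Logistic solver.** Newton–Raphson on internally standardized covariates;
  the raw age² column (scale ~10⁴) makes the information matrix nearly
  singular in double precision, while the MLE, fitted probabilities and
  delta-method variances are invariant to the affine rescaling. Coefficients
  are mapped back to the original scale for reporting. Convergence is
  declared at a score sup-norm below 1e−10·max(1, n/100), tight enough that
  the AAP-equals-raw-prevalence identity holds to 1e−10. Divergence guards
  detect separation (standardized coefficients beyond ±20) and name the
  offending covariate. A fused numba kernel accelerates the score and
  information accumulation when numba is importable; the pure-numpy fallback
  is bit-compatible to ~1e−12 and both paths are compared in the tests.
- **Bivariate normal tail.** Genz's rearrangement of the Drezner–Wesolowsky
  quadrature (Gauss–Legendre on the arcsine-transformed correlation, with an
  asymptotic expansion plus quadrature correction for |ρ| ≥ 0.925), accurate
  to ~1e−15 — validated in the tests against the closed form at the origin,
  scipy's multivariate normal CDF, and adaptive quadrature across the
  algorithm's switch point. It is implemented in-package because the r_f
  solver evaluates it inside a root-finder tens of thousands of times per
  study.
- **Root finding.** brentq on (−0.999, 0.999) with xtol 1e−10; the observed
  prevalence is checked against the attainable range first and the error
  reports that range.
- **Ties and degenerate inputs.** Duplicate (individual, phenotype, wave)
  rows are an error, not silently resolved. Sibling pairs in which either
  member has an unrecorded parent cannot be split into full vs half
  siblings; they are conservatively classified "other" (contributing to
  neither exposures nor counts) with a warning. Inbreeding is ignored in the
  kinship mapping — the cohorts targeted are outbred population samples and
  only the two canonical degree classes are used.

## The synthetic-data generator

The generator emulates the structure of a three-generation population
cohort. Families follow a template; the default — founder couple, two
children, the first child married to a founder spouse with one child, plus
one half-sibling via a second partner (8 members) — reproduces the target
cohort's reported median of two first-degree relatives per person and
contains every second-degree pair type (half-siblings, grandparent–
grandchild, avuncular). Generation baseline ages default to means 65/40/15
(SD 8/8/5), giving a cohort mean age near 42.

Liabilities are standardized: for each family, familial components G have
covariance A ⊗ C_familial (A the additive relationship matrix from the
pedigree module's kinship recursion, factored once per family and drawn as
chol(A)·Z·chol(C)ᵀ), and person-level residuals have covariance
R_within − C_familial, validated positive semidefinite with the offending
trait pair named otherwise. The diagonal of C_familial is each trait's
familial variance share (default 0.6 in the test configurations, in the
range twin studies report for these disorders); the off-diagonal *is* the
cross-trait r_f target, which is exactly the quantity the pipeline's
inversion estimates. With zero covariate effects on liability the threshold
Φ⁻¹(1−K) is exact; with nonzero effects the threshold is calibrated
numerically as the empirical quantile of the realized liabilities (tolerance
0.002 on K, checked).

Wave-level records emulate staggered assessment: lifetime cases receive a
uniformly drawn onset wave and appear as cases from that wave onward
(exercising the first-fulfilled age rule without modelling hazards);
per-wave missingness defaults to 0.10/0.20/0.30 across the three default
waves, reflecting growing attrition. Identical seeds give byte-identical
output.

What the generator does *not* emulate: assortative mating, ascertainment
into the cohort (every simulated person is observed, whereas one third of
the real cohort has no relative in the dataset), age- or sex-dependent
prevalence unless covariate effects are switched on, onset hazards, and
diagnostic misclassification beyond wave missingness. Passing recovery tests
therefore demonstrate the pipeline's statistical machinery under the
liability model's own assumptions, not robustness to these real-data
features.

## Known limitations

- **Exposure dilution attenuates r_f (and λ) relative to single-pair
  theory.** The estimator conditions on "≥ 1 affected relative", while the
  threshold-model inversion assumes conditioning on one specific affected
  relative. When relatives are plentiful or the co-disorder is common, the
  union event is weaker evidence of familial loading, so the exposed-group
  prevalence — and hence the recovered r_f — sits below the single-pair
  value. In the acceptance script's recovery study (30,000 families, true
  r_f = 0.30, prevalences 0.10/0.15, ~2.25 first-degree relatives per
  person) the pipeline recovers r̂_f ≈ 0.25; the per-pair conditional
  prevalence in the same simulated data matches the bivariate-normal
  prediction to three decimals, locating the gap entirely in the ≥1-affected
  exposure definition. Wave missingness contributes a further small
  attenuation through outcome misclassification. Estimates from this design
  should therefore be read as conservative lower bounds on the
  single-relative familial correlation, and confidence intervals around a
  materially attenuated point estimate will not cover the generating value.
- **Conservative λ inference**, as discussed above: realized one-sided
  type-I error is well below nominal for common exposures; the FDR layer
  inherits this conservatism.
- The inverse-variance combination weights are estimated from the same data
  as the components (weight noise is ignored, standard for this kind of
  pooling).
- The pipeline consumes already-derived wave-level case/control calls;
  instrument scoring and clinical case definitions are upstream and out of
  scope.
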