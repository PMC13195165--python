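# Methods

## The data and the model

The unit of analysis is the person × chromosome-arm telomere length
(csTL) table. A diploid genome has 92 telomere sites (22 autosomal pairs
× 4 arms + 4 sex-chromosome arms); after averaging the two haplotypes'
allele estimates, a person has up to 48 csTL values, of which 39
autosomal arms enter the models (the acrocentric short arms 13p/14p/15p/
21p/22p and the sex-chromosome arms are excluded because pseudo-homologous
and pseudo-autosomal recombination makes telomere-to-arm assignment
ambiguous there).

Aggregation rules, applied in order at the allele level:

1. drop calls with TL < 100 bp, TVR length < 0, or ambiguous arm mapping;
2. when building calls from read-level data, an allele cluster's TL is the
   75th percentile of its reads' TLs (type-7 linear interpolation — the
   upstream caller does not publish its quantile convention, so ours is
   fixed, configurable, and covered by an oracle test), subject to a
   minimum supporting-read count (4 for high-coverage samples > 25×, 3
   below 20×; the 20–25× gap is unspecified upstream and defaults to 3);
3. two or more allele estimates per arm are averaged; a single estimate
   is used as-is;
4. when an individual was sequenced twice, PacBio runs are preferred over
   ONT, then the run with more arm estimates, then lexicographic
   (platform, run id) — a deterministic generalization of the published
   per-sample choices.

The core model is a Gaussian LMM with crossed random effects,

y_{ia} = x_{ia}ᵀβ + u_i + b_a + ε_{ia},
u_i ~ N(0, σ²_ind), b_a ~ N(0, σ²_arm), ε ~ N(0, σ²_e),

optionally with a random batch intercept (batch is constant within
person) and a correlated random slope of centered age by arm (bivariate
arm effect with 2×2 covariance G). Fixed covariates are reference-coded:
female, never-smoker, AFR ancestry, and the most frequent batch are the
reference levels.

**Variance partitioning.** The share of variance (PVE) for the fixed
block is Var(Xβ̂)/T with T = Var(Xβ̂) + σ̂²_ind + σ̂²_arm + σ̂²_e, and
σ̂²_c/T for each random component — the marginal-R² (Nakagawa-style)
convention. Var(Xβ̂) uses the sample variance (n−1 denominator); at
cohort scale the distinction from the population variance is negligible.
A single covariate's contribution is the fixed-block PVE of a model with
only that covariate plus both random intercepts, and its p-value comes
from an ML likelihood-ratio test against the random-effects-only model.

**Likelihood-ratio tests.** Fixed-effect comparisons use ML fits;
random-effect comparisons use REML fits with identical fixed parts.
χ² = 2Δℓ clamped at zero, df = parameter-count difference; the
age-by-arm random slope adds a slope variance and a slope–intercept
covariance, hence df = 2. No 50:50 boundary mixture correction is
applied to variance-component tests — the plain χ² reference is
conservative, and fits at the boundary carry an explicit flag. P-values
that underflow are reported alongside a stable log₁₀ tail (exact forms
for df 1 and 2, leading asymptotic term otherwise).

## Fitting algorithm

β and σ²_e are profiled out; the remaining parameters are the
relative-covariance factors θ (standard-deviation ratios; lower-triangular
Cholesky factor of G/σ²_e for the bivariate arm effect), optimized by
L-BFGS-B under non-negativity bounds on the diagonal entries, followed by
a short Nelder–Mead polish that tightens the optimum past the
finite-difference gradient tolerance (making estimates invariant to
record order) and rescues occasional line-search failures.

Each objective evaluation exploits the layout of the penalized normal
equations: the individual-intercept block of ΛᵀZᵀZΛ + I is diagonal, so
a dense Schur complement over the small batch/arm block (≤ ~130 columns)
plus a rank-(p+1) second complement over [X y] yields the profiled
deviance, GLS β, its covariance, and all BLUPs in
O(n + I·q² + q³) per evaluation — about 5 ms at 78,000 records. The
n × n covariance matrix is only ever materialized inside the test-suite
oracle, which checks the profiled ML and REML objectives against a dense
multivariate-normal evaluation to 10⁻⁶ (observed agreement ~10⁻¹¹), and
variance components are additionally cross-checked against lme4 in R.

## Sign tests and their printing

Directional consistency across arms is tested with the exact one-sided
binomial tail P = Σ_{j≥k} C(n,j)/2ⁿ. The interval on p̂ = k/n is
reported as [L, 1] with L the one-sided 95% Clopper–Pearson lower bound;
this convention reproduces conventional printed bounds at k = 31, 29, 26
of 39 exactly, while at k = 39 it gives 0.93 where two-sided rounding
gives 0.91 — the convention is configurable (`two_sided_ci`) and
one-sided is the default. P-values print to one significant figure
(scientific below 10⁻⁴), e.g. 1.819 × 10⁻¹² → "2e-12",
1.47 × 10⁻⁴ → "0.0001". No multiplicity adjustment is applied across
arms; per-arm p-values are reported raw.

## The synthetic-data generator

Real csTL cohorts of this kind live behind controlled access, so the
generator reproduces the *statistical structure* the analyses assume,
not sequences. True TL at (person i, arm a, haplotype h) is

grand mean + arm deviation + individual intercept + batch offset
+ covariate effects + slope_a·(age_i − mean age) + e_{ia} + h_{iah},

floored at 1 bp. Design choices:

- **Variance-exact scaling.** Every component column (individual
  intercepts, arm deviations, batch offsets, each covariate effect,
  residuals) is affinely rescaled so its realized variance over the
  39-analysis-arm records equals exactly its configured fraction of
  total variance. Configured fractions are therefore realized fractions
  up to cross-component correlations, and recovery tests measure the
  estimator, not generator Monte-Carlo noise.
- **Defaults are the reference cohort's shares**: individual 8.9%, arm
  9.1%, batch 14.6%, age 3.7%, ancestry 3.1%, sex 1.1%, smoking 0.4%,
  BMI 0.2%; residual absorbs the rest. Total SD defaults to 1500 bp,
  which with the arm share gives arm-mean spreads of a few hundred bp
  around a 2.3–5.8 kb arm-mean gradient (3p/4q/13q/12q long; 16q/3q/20q/
  12p/17p short) — consistent with published arm rankings — and keeps
  floor events rare.
- **Residual placement.** The configured residual variance lives at the
  person × arm level, shared by both haplotypes; a separate haplotype
  deviation (default SD 250 bp) models allele heterogeneity. Placing the
  whole residual at the allele level would halve it after diploid
  averaging and silently shift every PVE denominator.
- **Age-slope coupling.** slope_a = −s₀·(mean_a/grand mean)^κ with κ = 1
  by default, then scaled so the age column carries its configured
  variance share: arms with longer mean TL shorten faster, giving the
  positive |slope|-vs-mean relation downstream tests look for. Because
  the slope varies by arm while the single-covariate model fits one
  slope, the age marginal R² recovers ≈ target/(1 + CV²(coupling)), a
  few tenths of a percentage point below the configured share.
- **Batch–ancestry confounding.** Each batch (center × platform ×
  coverage tier, weights mirroring a ~2300-person PacBio cohort) has its
  own ancestry mixing weights, including near-single-ancestry batches.
  The within-batch proportions are not published beyond margins and are
  free parameters. Under this confounding the ancestry share is not
  separately identifiable — recovery configurations set it to 0 and the
  batch share absorbs the technical axis, exactly the attenuation the
  residualized analysis of the real cohort shows.
- **Coverage and noise.** Reads per allele site are Poisson with
  tier-specific rates (defaults: 6 high-pass, 2.5 mid-pass, chosen to
  reproduce realistic arm-completeness of ~30–45 arms per person); read
  TL = true TL + N(0, 250 bp), floored at 0 rather than truncated
  (floor events are rare at default noise). Read lengths add a ~15 kb
  anchor offset. The depth matrix is low-rank batch structure (tier,
  platform, batch factors) plus noise; the average-TL estimate is the
  person's true mean TL plus a linear artifact in those factors.
- **Disease labels** are Bernoulli from logit P = intercept +
  log(OR_per_kb)·metric_kb (+ optional covariate terms); defaults give
  ~35% hypertension, ~12% T2D prevalence with protective ORs per kb near
  published point estimates (0.94–1.03).

What the generator does *not* emulate: sequence content, basecaller
error profiles (and hence the ONT-specific underestimation seen in real
data), haplotype phasing structure, non-Gaussian TL tails, and EHR
phenotyping noise. Passing tests therefore demonstrate correctness of
the estimators under the assumed variance structure, not robustness to
those real-data pathologies.

## Numerical and procedural choices

- Depth PCs: bins are z-scored before SVD (configurable); zero-variance
  bins dropped. The PC count k maximizes |corr(residual TL, age)| over a
  grid including k = 0; a larger k must improve the correlation by more
  than 0.01 (chance fluctuations from removing noise directions are
  O(1/√n)), and ties resolve to the smallest k.
- Batch residualization subtracts batch means; singleton batches get
  residual 0 with a warning.
- Outlier rule for disease models: mean/shortest TL beyond 3 cohort SDs,
  bounds computed once pre-exclusion (single pass, not iterated).
- Logistic fits use Newton with a BFGS fallback; (quasi-)separation
  raises a named error. Wald 95% CIs (profile-likelihood differences are
  negligible at cohort n). Arms with < 10 cases are flagged low-power
  but still reported.
- Down-sampling keeps each read with probability target/current
  (current = mean supporting reads per allele site unless given); error
  and correlation are computed only on person × arm pairs present in
  both the thinned and full sets, and levels with no shared arms are
  flagged undefined rather than zero.
- Per-stage pipeline seeds derive from the master seed by SHA-256,
  below 2³¹, so stages re-run identically in isolation.

## Problem sizes used by the test suite and acceptance script

Parameter-recovery runs use 2,000 individuals × 39 arms (~77,000
records) through the full read → call → QC → collapse pipeline; LRT null
calibration uses 500 replicates of 40 × 8 crossed layouts; dense-oracle
checks stay ≤ 200 records; coverage titration uses 36 samples at 30×
thinned to 25/20/15/10/5×; logistic OR recovery uses 50,000 individuals.
These sizes give sub-percent standard errors on the recovered shares
while a full run of suite plus acceptance script completes in a few
minutes on one CPU.

## Known limitations

- Exactly two crossed grouping factors plus an optional nested batch
  intercept and one random slope; no generalized (non-Gaussian) mixed
  models.
- Variance-component LRTs use the plain χ² reference (conservative at
  the boundary).
- The binomial CI convention at p̂ = 1 is ambiguous in the field's
  printed tables (0.92 vs our one-sided 0.93); both conventions are
  implemented.
- The generator's Gaussian tails understate the long right tail of real
  csTL distributions; flooring at 1 bp introduces a small truncation
  bias when the residual share approaches 1.
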