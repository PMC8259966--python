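# Methods

## State-space model of logit frequency dynamics

Each experimental line carries a latent trajectory ψ(t), the logit
frequency of the focal strain, modelled as a Gaussian process with
linear drift and Brownian-type variance growth. The implementation
assumes independent Gaussian increments: over a transfer interval of d
days, ψ gains N(s̄·d, (25/7)·σ_s²·d). This is slightly stronger than
specifying only the marginal law (mean and variance linear in t), but it
is the natural reading of selection coefficients being summed over time
on the logit scale, and it is what makes the joint covariance
cov(ψ(t₁), ψ(t₂)) = V(ψ₀) + (25/7)σ_s²·min(t₁,t₂) well defined and the
per-line likelihood a proper multivariate integral.

The drift is a linear model in treatment-level environmental covariates:
intercept (selection at constant 2.4 M), mean deviation μ_E, its square,
the environmental variance σ_E², the predictability ρ_E², and optionally
the signed autocorrelation ρ_E (the "full" model used to test whether
responses track predictability rather than transition size). The
variance of selection switches between σ₀² (constant treatments; it
absorbs drift and micro-environmental noise) and σ₁² (fluctuating). A
per-autocorrelation variance variant (σ₁² + θ₆ρ_E) exists; on realistic
designs it is weakly identified and may legitimately fail to converge,
which the fit reports through its `converged` flag rather than raising.

### The 25/7 correction

Salinity — and therefore selection — is constant within a transfer and
redrawn at transfers. Over a weekly cycle of a 3-day and a 4-day
interval, the cumulative logit change has variance (3² + 4²)σ_s² against
7σ_s² under daily redraws; the ratio Σd²/Σd = 25/7 inflates the variance
but not the mean. The factor is computed from the schedule, not
hard-coded, and generalises to other cycles (`variance_inflation_factor`).

### Observation model

Counts at the two loci are conditionally independent binomials given ψ.
The chloroplast success probability is logit⁻¹(ψ). The ITS2 probability
is α + β·logit⁻¹(ψ) with (α, β) = (0.19, 0.79) by default — the linear
calibration measured on reference mixtures, which absorbs the carriage
of the C-type ITS2 haplotype by ~20% of strain-A reads. The calibration
can instead be estimated jointly with the state-space fit
(`ModelSpec(estimate_calibration=True)`); the default keeps it fixed
from the calibration stage, since the mixture series measures it far
more directly than the time series does. Timepoints with zero depth at
both loci carry no information and are dropped from the latent vector;
lines lost to attrition contribute observations only up to their last
transfer.

### Laplace approximation and optimisation

Per line, the latent vector at its observed days is integrated out by a
Laplace approximation: an inner Newton ascent (Fisher-scoring metric,
backtracking line search, gradient tolerance 10⁻⁶, at most 100
iterations) finds the joint-density mode, and the Gaussian curvature
correction uses the true Hessian there (falling back to the Fisher
curvature in the rare case it is not negative definite). Lines sharing a
sequencing-day pattern and treatment are processed as one batched matrix
operation, and inner solutions are warm-started across outer iterations.

The outer maximisation runs L-BFGS-B on the fixed effects and
log-transformed variance components (so boundary estimates such as
V(ψ₀) ≈ 0 are representable; the log-scale floor is e⁻²⁵), with
central-difference gradients using parameter-relative steps, and up to
four restarts — restarting clears the quasi-Newton curvature memory,
which helps when stiff fixed-effect directions coexist with a flat
boundary-variance direction. Standard errors come from the inverse
numerical Hessian (central differences of the gradient, relative step
10⁻³), inverted on its well-conditioned eigenspace only and
delta-transformed to the natural variance scale; a parameter resting on
its floor has no curvature and reports a missing standard error instead
of contaminating the others.

Accuracy: on scalar-latent instances the Laplace value is within 10⁻²
log-likelihood units of 41-node adaptive Gauss–Hermite quadrature when
the prior carries about one transfer's worth of process noise. The
intrinsic Laplace error grows with prior variance and shrinking depth —
around 0.02–0.05 for unit-to-tenfold prior variances at depths ≤ 50,
driven by the skewness of the binomial-logit posterior at extreme
frequencies. At the experiment's depths (hundreds to thousands of reads)
the approximation error is orders of magnitude below the sampling noise.

### Short-term per-transfer model

For consecutively sequenced transfers the salinities on both sides are
known, and selection over the single transfer is modelled by a bivariate
reaction norm s(E_prev, E_cur) = a′ + b′E + c′E² + dE_prev + eE_prev² +
fE·E_prev, optionally with log₁₀-density and logit-frequency covariates.
Both endpoint logits are latent with the same dual-locus observation
model; ψ_cur | ψ_prev ~ N(ψ_prev + d·s, d²σ_s²) and the prior on ψ_prev
is flat, so likelihoods are defined up to a constant — sufficient for
the nested LR tests (current terms, past terms, density, frequency) and
for the coefficient estimates. Each latent pair is integrated by a
bivariate Laplace approximation with an explicit 2×2 solve.

## Reaction norms and induced distributions

For s(E) = a + bE + cE² and E ~ N(μ, σ²):

- mean: a + bμ + c(μ² + σ²); with c < 0 the variance term is a pure
  Jensen-inequality reduction, independent of μ.
- variance: σ²(b² + 4bcμ + 2c²(σ² + 2μ²)). This is the exact Gaussian
  moment identity for var(bE + cE²). A transcription of this formula
  circulates with the final factor written as (2μ + σ²), which is
  dimensionally inconsistent; both coincide at μ = 0, the case all the
  headline numbers use, and this package implements the exact form.
- distribution: for c ≠ 0, s = s_max + cσ²·W with W ~ χ²₁(λ),
  λ = (μ + b/2c)²/σ² — a displaced, (negatively) scaled noncentral
  chi-square, left-skewed for concave norms; Gaussian when c = 0.

The bivariate norm's moments under the binormal law of two successive
AR(1) salinities are available both in closed form (Isserlis expansion)
and by seeded Monte Carlo (10⁶ draws by default); the two routes serve
as mutual cross-checks, and the mean is exactly affine in ρ with slope
f·σ².

Tolerance curves: selection predicted from two per-strain growth-rate
curves is their difference on a salinity grid (default 0–4.8 M, step
0.1 M), least-squares fitted by a quadratic in the deviation from 2.4 M.
The tolerance-breadth analogue of a concave norm is reported as
1/√(−c) — the quantity with salinity units; note that some descriptions
define it as 1/−c while reporting values consistent with 1/√(−c).

## Barcode typing

Diagnostic sites are ranked by the multi-allele Nei G_ST = 1 − H_S/H_T
over {A, T, G, C, gap}, with H_T computed from equal-weight pooled
frequencies (each strain contributes 1/I regardless of read depth, as
the estimator is defined) and H_S the unweighted mean within-strain
heterozygosity; monomorphic sites return 0 by convention, and sites
lacking coverage in a strain are skipped with a warning. Thresholds are
strict inequalities (> 0.8 chloroplast-style, > 0.2 ITS2-style). No
explicit linkage-disequilibrium filter is applied — the thresholds are
the selection rule, and co-occurrence on reads is a diagnostic, not a
filter. Haplotypes are per-strain majority bases at the selected sites;
a haplotype carried by several strains is tagged shared, its per-strain
carriage estimated as the minimum per-site base frequency (exact under
complete LD among the selected SNPs, which per-site counts cannot
verify). Read classification is exact string matching at the SNP
positions: mismatching reads are dropped and counted, reads too short to
cover the sites counted separately, and matched + dropped +
non-covering always equals the input total. The shared ITS2 haplotype
counts toward the C allele; the (α, β) calibration absorbs the strain-A
carriage downstream rather than reassigning reads. FASTQ qualities are
read but unused — upstream filtering is assumed, and a minimum-length
check stands in for trimming.

## Synthetic experiments

The generator's defaults are the experimental design itself: constant
treatments at 0.8/2.4/3.2 M (5 lines each), AR(1) treatments at
ρ ∈ {−0.5, 0, 0.5, 0.9} with mean 2.4 M and unit variance (40 lines
each), 37 transfers alternating 3/4 days (3-day interval first, as a
convention — the schedule's phase is configurable), sequencing at
transfers {6, 7, 8, 14, 21, 22, 23, 30, 37}, and generating parameters
equal to the published point estimates. Salinities are clamped to the
physical [0, 4.8] M range of the media-mixing robot; at unit variance
this censors ~1.6% of draws and shaves a few percent off the realised
variance, which the environment tests account for explicitly.

Read depths are overdispersed (gamma-mixed Poisson with shape 5 around
means 1422 and 3407) — only the mean depths are documented
for the real data, and shape 5 gives a realistic coefficient of
variation ~0.45 without producing zero-depth cells at these means.
Attrition is a phenomenological per-transfer death probability, 0.037
for fluctuating lines (so ~25% survive 37 transfers, matching the
decline from ~160 to ~40 analysable lines) and 0.005 for constant lines;
deaths are independent across lines, a deliberate simplification of the
demography-driven extinctions in the real experiment. A master seed
spawns per-line child generators, so single lines are reproducible in
isolation.

Macroscopic mode draws latent increments directly from the fitted
Gaussian process — the exact model the inference assumes, which is what
parameter-recovery and coverage tests require. Mechanistic mode computes
per-transfer selection from a reaction norm applied to the realised
salinities plus optional Gaussian residual noise; it reproduces the
Gaussian-propagation mean slope across lines and bridges the prediction
layer to the macroscopic description. What neither mode emulates:
genetic drift as a frequency-dependent process (its contribution is
absorbed phenomenologically into σ₀²), density regulation and
demographic feedback on extinction, PCR/sequencing artefacts beyond
binomial sampling, or linkage breakdown between the two loci. Passing
recovery tests therefore demonstrates correctness of the inference under
the model's own assumptions, not robustness to these real-data features.

Read-level emission writes FASTQ records carrying the reference
haplotype bases at the SNP positions with random filler elsewhere,
closing the loop synthetic counts → reads → classified counts exactly at
zero contamination.

## Problem sizes in the test and acceptance suites

The distribution-level checks use 10⁵–10⁶ Monte-Carlo draws with fixed
seeds and 3–4 MC-standard-error tolerances. Parameter recovery runs one
full-design replicate (≈150 lines after attrition) plus twenty
scaled-down replicates (one constant and two fluctuating treatments, 30
lines) for the 2-standard-error coverage check; LR-test calibration uses
200 replicates of a two-treatment, 40-line null design. These sizes were
chosen so each check resolves the property it tests — a coverage
proportion, a 5% rejection rate — with binomial error well inside the
asserted bands.

## Known limitations

- The Laplace approximation is biased by posterior skewness at very low
  depth combined with diffuse priors (see accuracy note above); fully
  Bayesian or quadrature-based marginals are out of scope.
- The per-transfer model's flat prior on the initial logit makes its
  likelihood improper in the absolute sense; only differences matter.
- Standard errors are curvature-based; for variance components near
  their boundary the Gaussian approximation to the sampling distribution
  is one-sided and the reported (delta-transformed) standard errors are
  small almost by construction — profile or bootstrap intervals would be
  the upgrade.
- The G_ST site selector treats sites independently; haplotype-aware
  panels with partial LD between selected SNPs will misestimate carriage
  of shared haplotypes.
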