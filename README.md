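# fluctsel

Inference and prediction of randomly fluctuating selection in
serial-transfer competition experiments.

## The problem

When two genotypes compete in an environment that fluctuates randomly —
here, two strains of the halotolerant micro-alga *Dunaliella salina*
(CCAP 19/15, "C", versus CCAP 19/12, "A") under salinity regimes with
controlled mean, variance and autocorrelation — the strength of selection
itself becomes a random process. Its mean and variance per unit time are
the quantities that population-genetic theory in stochastic environments
is parameterised by, yet they are rarely measured directly. This package
implements, end to end, the machinery needed to estimate them from
amplicon-sequencing time series and to test whether they can be
*predicted* from simpler measurements: selection reaction norms estimated
in constant environments, and per-strain tolerance curves.

It is a library first: the importable API plus the narrative scripts in
`examples/` are the main interface, with a thin `fluctsel` command-line
wrapper for whole-pipeline runs.

## The model

Strain C's logit frequency ψ = ln(p/(1−p)) in line *i* is a latent
Gaussian process over time *t* (days),

```
E[ψ(t)]          = ψ̄₀ + s̄ t
cov[ψ(t₁),ψ(t₂)] = V(ψ₀) + (25/7) σ_s² min(t₁,t₂)
s̄  = θ₀ + θ₁ μ_E + θ₂ μ_E² + θ₃ σ_E² + θ₄ ρ_E²
σ_s² = σ₀² (constant)  or  σ₁² (fluctuating salinity)
```

where μ_E, σ_E², ρ_E are the mean (as deviation from 2.4 M NaCl),
variance and lag-1 autocorrelation of the line's AR(1) salinity regime,
and ρ_E² is its predictability. The factor 25/7 = Σd²/Σd corrects the
variance for selection being redrawn once per transfer and held constant
within the alternating 3- and 4-day intervals. Observations are read
counts at two barcode loci, conditionally independent binomials given ψ:
the chloroplast locus reports p directly, the nuclear ITS2 locus reports
α + βp (α = 0.19, β = 0.79) because its C-type haplotype is also carried
by ~20% of strain A. The latent vectors are integrated out by a Laplace
approximation and the marginal likelihood maximised by quasi-Newton
descent; Wald and likelihood-ratio tests, delta-method confidence
intervals, latent-trajectory reconstruction and a short-term
per-transfer model (bivariate reaction norm in current and previous
salinity) complete the inference layer.

The prediction layer propagates a quadratic selection reaction norm
s(E) = a + bE + cE² through a Gaussian environment: mean selection
a + bμ + c(μ² + σ²) (a Jensen-inequality reduction when c < 0), variance
σ²(b² + 4bcμ + 2c²(σ² + 2μ²)), and a displaced noncentral-χ²₁
distribution of selection coefficients.

## Worked example

`python examples/02_reaction_norm_predictions.py` evaluates the reaction
norm estimated in constant salinities and prints:

```
selection at 2.4 M (constant):       0.0927 per day
optimal salinity:                    0.99 M
maximal selection:                   0.16 per day
tolerance-breadth analogue 1/sqrt(-c): 5.3 M

under E ~ N(0, 1):
  mean selection: 0.0574 per day (Jensen reduction c*sigma2 = -0.0353)
  selection variance: 0.0124 per day^2
  distribution: displaced-noncentral-chi-square, noncentrality 1.98

variance inflation for the 3/4-day schedule: 3.5714 (= 25/7)
```

Strain C is maximally favoured (s = 0.16/day) near 1 M NaCl; in a
unit-variance fluctuating environment its mean advantage drops from
0.093 to 0.057 per day purely because the norm is concave, and salinity
fluctuations alone generate a selection variance of 0.012 per day² —
about an order of magnitude less than what the state-space model
estimates in fluctuating treatments, which is the package's central
quantitative contrast. The other examples cover environment simulation,
barcode classification, the full state-space fit, the per-transfer
model, and the pipeline.

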