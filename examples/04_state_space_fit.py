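"""Fit the state-space model to a synthetic serial-transfer experiment.

Simulates a reduced design (one constant + two fluctuating treatments)
from the published estimates as generating truth, fits the latent
Gaussian logit-frequency model by Laplace-approximated maximum marginal
likelihood, and prints the recovered parameters with delta-method
confidence intervals for mean selection.
"""

from fluctsel import (
    ExperimentConfig,
    ModelSpec,
    TreatmentSpec,
    fit,
    generate_experiment,
    lines_from_frames,
    mean_selection_ci,
)

cfg = ExperimentConfig(
    treatments=[
        (TreatmentSpec(2.4, 0.0, 0.0, constant=True), 6),
        (TreatmentSpec(2.4, 1.0, 0.0), 15),
        (TreatmentSpec(2.4, 1.0, 0.9), 15),
    ],
)
exp = generate_experiment(cfg, seed=11)
lines = lines_from_frames(exp.counts, exp.treatments)
model = ModelSpec(mean_terms=("intercept", "sigma2", "rho2"))
res = fit(lines, model=model)

print(f"{len(lines)} lines with data, log marginal likelihood {res.loglik:.1f}, "
      f"converged: {res.converged}\n")
print(res.summary().to_string(index=False, float_format=lambda v: f"{v: .4g}"))

print("\nmean selection in fluctuating treatments (delta-method 95% CI):")
for rho in (0.0, 0.5, 0.9):
    est, lo, hi = mean_selection_ci(res, rho)
    print(f"  rho = {rho:3.1f}: s_bar = {est: .4f}  [{lo: .4f}, {hi: .4f}]")
print("\nPositive predictability (rho^2) effects raise mean selection toward "
      "its constant-environment value; the fluctuating-treatment selection "
      "variance (sigma1_sq) exceeds the constant one (sigma0_sq).")
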