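"""Short-term selection across single transfers with known salinities.

Simulates pairs of consecutively sequenced transfers from a bivariate
selection reaction norm (current + previous salinity + interaction),
fits the per-transfer latent model, and runs the nested LR tests for
current-salinity, past-salinity, density and frequency effects.
"""

import numpy as np
from scipy import special

from fluctsel import fit_transfer_model, transfer_lr_tests
from fluctsel.reaction_norms import ReactionNormBi
from fluctsel.synthetic import simulate_transfer_pairs

true_norm = ReactionNormBi(0.05, -0.10, -0.04, 0.06, 0.02, 0.08)
pairs = simulate_transfer_pairs(true_norm, n_pairs=150, sigma_s_sq=0.01,
                                depth=3000, seed=8)

res = fit_transfer_model(pairs)
print(f"fitted {res.n_pairs} transfer pairs, loglik {res.loglik:.1f}\n")
print(f"{'term':>12} {'estimate':>9} {'truth':>7} {'se':>7}")
truths = dict(zip(res.terms, (true_norm.a, true_norm.b, true_norm.c,
                              true_norm.d, true_norm.e, true_norm.f)))
for term in res.terms:
    print(f"{term:>12} {res.params[term]:9.4f} {truths[term]:7.3f} {res.se[term]:7.4f}")
print(f"{'sigma_s_sq':>12} {res.params['sigma_s_sq']:9.4f} {0.01:7.3f} "
      f"{res.se['sigma_s_sq']:7.4f}")

pairs["log10_density"] = np.random.default_rng(0).uniform(3, 5.8, len(pairs))
pairs["logit_freq"] = special.logit(np.clip(pairs.n0 / pairs.N0, 0.01, 0.99))
tests = transfer_lr_tests(pairs, with_density=True, with_freq=True)
print("\nnested LR tests:")
for name, t in tests.items():
    print(f"  {name:18s} stat {t.statistic:7.2f}  df {t.df}  p {t.p_value:.2g}")
print("\nCurrent- and past-salinity terms are detected (they generated the "
      "data); density and frequency, which did not, are not.")
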