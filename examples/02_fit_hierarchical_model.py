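"""Fit the hierarchical Bayesian SDT model to one synthetic condition.

Generates a 20-subject condition dataset from a known truth, fits the
binomial-probit hierarchy by MCMC (fast profile), and prints posterior
summaries with convergence diagnostics.
"""

import numpy as np

from hbsdt import (
    PriorConfig,
    SamplerConfig,
    Valence,
    convergence_report,
    derive_sigma,
    posterior_summary,
    sample_posterior,
)
from hbsdt.simulate import CellTruth, generate_condition

truth = CellTruth(mu_c=0.3, mu_d=2.0, sigma_c=0.3, sigma_d=0.3)
rng = np.random.default_rng(1)
dataset, _ = generate_condition(
    truth, "melancholic", Valence.POSITIVE, rng, n_subjects=20
)

cfg = SamplerConfig(n_chains=2, n_iterations=2000, adapt_iterations=1000, seed=1)
samples = derive_sigma(sample_posterior(dataset, PriorConfig(), cfg))

print(f"{'parameter':<10}{'truth':<8}{'mean':<8}{'sd':<8}95% HPD")
for name, true_val in [("mu_c", truth.mu_c), ("mu_d", truth.mu_d),
                       ("sigma_c", truth.sigma_c), ("sigma_d", truth.sigma_d)]:
    s = posterior_summary(samples, name)
    print(f"{name:<10}{true_val:<8.2f}{s['mean']:<8.3f}{s['sd']:<8.3f}"
          f"({s['hpd_lower']:.3f}, {s['hpd_upper']:.3f})")

report = convergence_report(samples)
print(f"\nmax R-hat {report.max_rhat():.4f} (threshold {report.rhat_threshold}); "
      f"convergence {'PASS' if report.overall_pass else 'FAIL'}")
print(
    "\nmu_c/mu_d are the group-mean bias and discriminability; sigma_c and\n"
    "sigma_d the inter-subject spread.  Group means are well recovered at\n"
    "this design size; group SDs are weakly identified from 54-trial\n"
    "subjects, so their intervals are wide and can sit low (see\n"
    "docs/methods.md)."
)
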