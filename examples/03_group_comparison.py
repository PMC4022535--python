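"""Compare two groups with the 95% HPD difference (HPDd) rule.

Generates two groups that truly differ in mean bias, fits each
independently, and tests the difference distribution of mu_c: the groups
are called significantly different when the 95% HPD of the paired
draw-wise difference excludes zero.
"""

import numpy as np

from hbsdt import (
    PriorConfig,
    SamplerConfig,
    Valence,
    compare_groups,
    derive_sigma,
    sample_posterior,
    violin_summary,
)
from hbsdt.simulate import CellTruth, generate_condition

cfg = SamplerConfig(n_chains=2, n_iterations=2000, adapt_iterations=1000, seed=0)
rng = np.random.default_rng(1)

data_mel, _ = generate_condition(
    CellTruth(mu_c=0.30, mu_d=2.2, sigma_c=0.3, sigma_d=0.3),
    "melancholic", Valence.POSITIVE, rng, n_subjects=20,
)
data_nonmel, _ = generate_condition(
    CellTruth(mu_c=-0.10, mu_d=2.4, sigma_c=0.3, sigma_d=0.3),
    "non_melancholic", Valence.POSITIVE, rng, n_subjects=20,
)

s_mel = derive_sigma(sample_posterior(data_mel, PriorConfig(), cfg))
s_nonmel = derive_sigma(sample_posterior(data_nonmel, PriorConfig(), cfg))

for param in ("mu_c", "mu_d", "sigma_c"):
    comp = compare_groups(s_mel, s_nonmel, param)
    verdict = "significant" if comp.significant else "not significant"
    print(f"{param:<8} HPDd = ({comp.hpdd.lower:+.3f}, {comp.hpdd.upper:+.3f})  "
          f"mean diff {comp.mean_difference:+.3f}  -> {verdict}")

v = violin_summary(s_mel.flat("mu_c"))
print(f"\nmelancholic mu_c quartiles: {v.q1:.3f} / {v.median:.3f} / {v.q3:.3f}")
print(
    "\nA positive mu_c difference means the first group is more 'no'-leaning.\n"
    "The true bias gap (0.40) should be flagged; the small d' gap may not be."
)
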