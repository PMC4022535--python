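"""End-to-end pipeline on a synthetic three-group study.

Generates a full study calibrated to the published aggregate rates, fits
all nine group x condition cells (fast profile), and prints the
significant group comparisons and convergence status.
"""

from hbsdt import RunConfig, SamplerConfig, run_full_analysis
from hbsdt.simulate import generate_study, reference_truth

study = generate_study(reference_truth(seed=0))
cfg = RunConfig(
    sampler=SamplerConfig(n_chains=2, n_iterations=2000,
                          adapt_iterations=1000, seed=0),
)
report = run_full_analysis(cfg, study.subjects)

print(f"fitted cells: {len(report.cells)}; "
      f"comparisons: {len(report.comparisons)}")
print(f"all cells converged (R-hat): {report.provenance['convergence_ok']}\n")

sig = [c for c in report.comparisons if c["significant"]]
print(f"{len(sig)} significant comparisons (uncorrected):")
for c in sig:
    print(f"  {c['condition']:<9} {c['parameter']:<8} "
          f"{c['group_a']} vs {c['group_b']}: "
          f"HPDd ({c['hpdd_lower']:+.3f}, {c['hpdd_upper']:+.3f})")

print(
    "\nEach line is a group pair whose 95% HPD difference interval for that\n"
    "parameter excludes zero in that signal condition.  With truth taken\n"
    "from the published aggregate rates, expect discriminability gaps\n"
    "involving the melancholic group (e.g. neutral-condition mu_d)."
)
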