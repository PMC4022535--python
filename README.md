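# hbsdt — hierarchical Bayesian signal detection for go/no-go data

`hbsdt` analyses affective go/no-go (AGN) task data — counts of hits,
misses, false alarms and correct rejections per subject and block — with
equal-variance Gaussian signal detection theory (SDT), estimated
hierarchically across subjects by MCMC.  It is written for researchers in
psychophysics and clinical neuropsychology who want subject-level and
group-level posteriors of response **bias** and **discriminability**
rather than group averages of point estimates, including studies
contrasting diagnostic groups (e.g. melancholic vs non-melancholic
depression vs controls).

## The model

For subject *i* in one group × signal-valence condition, with hit count
*H<sub>i</sub>* of *S<sub>i</sub>* signal trials and false-alarm count
*F<sub>i</sub>* of *N<sub>i</sub>* noise trials:

```
H_i ~ Binomial(S_i, Φ(d_i/2 − c_i))       F_i ~ Binomial(N_i, Φ(−d_i/2 − c_i))
c_i ~ Normal(μ_c, λ_c⁻¹)                  d_i ~ Normal(μ_d, λ_d⁻¹)
μ  ~ Normal(0, 10³)                       λ  ~ Gamma(0.001, 0.001)
```

*d′* is the probit separation of signal and noise strength distributions;
*c* the criterion location (negative = "yes"-leaning); σ = λ<sup>−1/2</sup>
the inter-subject spread.  Posteriors come from a Metropolis-within-Gibbs
sampler (2 chains × 10,000 draws by default) with two-chain R̂ and Geweke
convergence diagnostics.  Groups are compared with 95% highest posterior
density intervals of the draw-wise difference (HPDd): an interval
excluding zero is declared a significant difference.  A synthetic-data
generator reproduces the full AGN block design (3 groups × 20 subjects,
18 scored blocks of 9 signal + 9 noise trials, pooled or unpooled noise
valences, occasional missing trials) for testing and calibration.
`docs/methods.md` has the full account.

## Worked example

```sh
python examples/02_fit_hierarchical_model.py
```

fits a 20-subject synthetic condition with known truth
(μ_c = 0.3, μ_d = 2.0, σ = 0.3) and prints:

```
parameter truth   mean    sd      95% HPD
mu_c      0.30    0.258   0.079   (0.104, 0.414)
mu_d      2.00    2.083   0.076   (1.934, 2.229)
sigma_c   0.30    0.317   0.068   (0.197, 0.455)
sigma_d   0.30    0.099   0.066   (0.015, 0.227)

max R-hat 1.0020 (threshold 1.1); convergence PASS
```

Group means are recovered inside their 95% HPD intervals; σ_d illustrates
the weak identification of group SDs at 54 trials per subject (see
`docs/methods.md`).  The other examples cover the classical d′ table
(`01`), HPDd group comparison (`03`) and the full nine-cell pipeline with
all pairwise comparisons (`04`).

A command-line layer wraps the same pipeline:

```sh
hbsdt simulate --seed 1 --out study.csv
hbsdt report study.csv --outdir results/ --fast
hbsdt sensitivity study.csv --outdir sens/ --fast
```

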