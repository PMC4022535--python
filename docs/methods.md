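# Methods

## The model

`hbsdt` analyses block-structured go/no-go data with equal-variance
Gaussian signal detection theory (SDT), fitted hierarchically across
subjects.  For each group × signal-valence cell, subject *i* contributes a
hit count *H<sub>i</sub>* out of *S<sub>i</sub>* signal trials and a
false-alarm count *F<sub>i</sub>* out of *N<sub>i</sub>* noise trials:

    H_i ~ Binomial(S_i, Φ(d_i/2 − c_i))
    F_i ~ Binomial(N_i, Φ(−d_i/2 − c_i))
    c_i ~ Normal(μ_c, λ_c⁻¹)        d_i ~ Normal(μ_d, λ_d⁻¹)
    μ_c, μ_d ~ Normal(0, 1000)      λ_c, λ_d ~ Gamma(0.001, 0.001)

where Φ is the standard-normal CDF, *d<sub>i</sub>* is discriminability
(probit separation of signal and noise strength distributions) and
*c<sub>i</sub>* is the response criterion (negative = "yes"-leaning).
Group standard deviations are derived per draw as σ = λ<sup>−1/2</sup>.
Each condition is modelled separately and the two noise valences in a
signal condition are pooled by default; an unpooled mode keeps them apart
for sensitivity analysis.

A literal uniform prior over unbounded real means is improper, so the
"reference prior" configuration is operationalised as the vague conjugate
family above (precision 0.001 normals on means, Gamma(0.001, 0.001) on
precisions).  `PriorConfig` makes a narrower-prior robustness check a
parameter change, not a code change.  Subject discriminability is not
truncated at zero: the Gaussian subject-level model permits negative
*d<sub>i</sub>*.

## Sampling

The sampler is Metropolis-within-Gibbs, chosen so that the retained draws
form a Markov chain whose invariant distribution is exactly the joint
posterior:

* vectorised Gaussian random-walk updates of the subject vectors *c* and
  *d*, several sweeps per iteration, with per-subject proposal scales
  adapted toward a 20–50% acceptance rate during a discarded warm-up phase
  (default 2,000 iterations) and frozen afterwards;
* conjugate Gibbs draws for μ (Normal) and λ (Gamma);
* joint translation moves that shift μ and all subject values together —
  the subject-level Normal terms are translation invariant, so the move
  directly mixes the slow global-level mode of the centred hierarchy;
* non-centred scale moves: a 1-D Metropolis step on log λ that jointly
  rescales subject deviations, holding u_i = √λ(x_i − μ) fixed.  The
  Normal terms and Jacobians cancel, leaving likelihood × Gamma(λ) × λ in
  the acceptance ratio.  This mixes the variance-funnel mode; without it
  (and the translation moves) the Geweke diagnostic correctly flagged slow
  relaxation in roughly a quarter of well-specified runs.

Chains are initialised at classical per-subject probit estimates
(extreme rates adjusted by the 1/(2·total) rule), with group precisions
floored at variance 0.01 so degenerate cohorts still start at a finite
log-joint.  Binomial tail probabilities use the log-CDF directly, so the
log-joint is finite for any valid state.  One master seed is supplied;
chain *k* uses seed + *k*.  Runs are bit-reproducible given the
configuration.

Defaults mirror the emulated study budget: 2 chains × 10,000 retained
draws, with a 5,000-draw burn-in applied to positive-condition fits (the
remedy historically applied when early/late segment means of
positive-condition chains disagreed).  A fast profile (2 × 2,000 after a
1,000-draw warm-up) exists for replicate-heavy simulation studies and CI;
replicate-based tests in this repository use the fast profile and the
convergence check uses the full budget.

## Convergence diagnostics

R̂ is the classic (non-split) two-chain Gelman–Rubin potential scale
reduction, with the conventions: all-identical draws give 1.0, zero
within-chain variance with distinct chains gives +∞.  A split-R̂ variant is
available behind a flag (it also detects within-chain trends that the
plain two-chain form cannot).  Threshold: 1.1.

The Geweke diagnostic compares the mean of the first 10% of each chain
with the mean of its last 50%, with segment variances estimated by
non-overlapping batch means (~√n batches), an autocorrelation-consistent
estimate of the spectral density at zero.  Per-parameter flags use the
nominal |z| < 1.96.  The *cell-level* verdict cannot use that rule: a
fitted cell yields ~90 z-scores, so an any-parameter rule at the nominal
level flags essentially every converged run.  The cell verdict therefore
applies a Bonferroni correction across all z-scores in the report at a
small family-wise level (`cell_alpha` = 0.005, so a nine-cell study
retains a conventional overall false-flag rate), using a Student-t
reference whose degrees of freedom match the batch count of the shorter
early segment (the z denominators carry ~30-df noise at the default
budget).  The strict any-parameter rule remains available as
`geweke_pass_nominal`.  When the Geweke verdict fails, the report
recommends applying a burn-in.

## Interval summaries and group comparisons

95% central credible intervals are empirical 2.5/97.5% quantiles (linear
interpolation).  The 95% HPD interval is the narrowest contiguous window
of sorted draws containing ⌈0.95·n⌉ of them, ties broken toward the lowest
start.  Groups are fitted independently, chains concatenated post burn-in,
and the difference distribution for a parameter pairs draws by index
across the two independent fits (a resampling mode exists behind a flag).
A group difference is declared "significant" when the 95% HPD of the
difference excludes zero — reported uncorrected for multiplicity, with an
explicit note in the report.  σ comparisons act on the per-draw
λ<sup>−1/2</sup> values (transform, then summarise — never the reverse).
Violin summaries carry quartiles plus a Gaussian KDE (Silverman bandwidth)
on a 128-point grid spanning the draw range ± 3 bandwidths.

## The synthetic generator

The generator emulates the study design the analysis assumes: three
diagnostic groups (melancholic, non-melancholic, control) of 20 subjects;
18 scored blocks per subject cycling through the six legal signal/noise
valence pairings three times (training blocks are never represented);
9 signal and 9 noise trials per block, so 54 + 54 trials per subject per
pooled condition.  Per cell, subject parameters are drawn from the group
Normals and block counts from the binomial forward model.  Missing trials
are modelled as independent uniform dropout before the binomial draw
(default rate 0.001 ≈ a few trials per group-condition out of 1,080,
matching the shortfalls visible in the published totals).  Subject
parameters are drawn independently across conditions because conditions
are modelled separately downstream; a cross-condition correlation knob is
deliberately absent until there is an analysis that would consume it.

`reference_truth()` sets each cell's (μ_c, μ_d) to the classical
criterion/d′ of the published 2-dp aggregate rates, with σ_c = σ_d = 0.3 —
a conventional value, stated as a convention: the emulated study reports
only posterior σ *contrasts*, never the σ values themselves, so the true
inter-subject spread is unknown.

What passing tests on generated data do **not** show: real AGN data have
sequential (trial-order) effects, fatigue and block-order effects,
cross-condition correlation within subject, and non-binomial lapses; the
generator has none of these, so recovery results here quantify estimator
behaviour under the model's own assumptions, not robustness to their
violation.

## The published aggregate table

The package ships the published group × valence aggregate counts and the
published 2-dp rate/d′ columns for the three-group melancholia study it
emulates.  Two conventions coexist in that table and both are documented
here rather than hidden:

* the printed d′ column follows from probit-differencing the *printed*
  2-dp rates in 8 of 9 cells; the melancholic/positive cell prints the
  value implied by unrounded rates (2.33 vs 2.34), a 0.01 discrepancy;
* the printed rate columns are *not* all reproducible from the printed
  counts: three of 18 values (non-melancholic/negative false-alarm rate,
  both control/negative rates) sit 0.01 away under any rounding
  convention, consistent with rates having been computed from per-subject
  data before pooling.  The per-subject data are not deposited, so the
  count → rate step is checked on the 15 conforming values and the
  rate → d′ step on all cells.

`rates_from_counts` exposes both rounded (2-dp, half-away-from-zero) and
unrounded rates so either convention can be applied explicitly.

## Numerical choices and problem sizes

* Extreme per-subject rates (0 or 1 over 54 trials) are adjusted by the
  1/(2·total) rule before classical probit estimates.
* The HPD tie-break (lowest starting index) only matters for discrete
  ties, which occur with probability zero for continuous draws.
* Replicate-based simulation checks (parameter recovery, null
  calibration, simulation-based calibration) use 20–50 replicates at the
  fast profile with 10–20 subjects; the convergence and oracle checks use
  the full 2 × 10,000 budget.  These sizes are the package's test
  conventions, chosen to make the checks sharp at desk scale.

## Known limitations

* Group-SD inference is weakly identified at this design size: with 54 +
  54 trials the binomial sampling noise on a subject's d′ (~0.35 SD) is
  comparable to plausible true spreads, and under the vague
  Gamma(0.001, 0.001) precision prior the posterior for σ_d pulls low
  (in simulations with true σ_d = 0.3 and 20 subjects, 95% HPD
  frequentist coverage of σ_d is ~80% and posterior means average ~0.23).
  This is a property of the conventional vague-Gamma setup the package
  reproduces — the usual argument for half-Cauchy priors on group SDs —
  not of the sampler; group-mean inference is unaffected (see the
  recovery and calibration tests).  Narrower or alternative priors are a
  `PriorConfig` away.
* The equal-variance SDT assumption is untestable from a single
  (hit, false-alarm) pair per subject; unequal-variance and ROC models are
  out of scope.
* The model ignores trial-to-trial dynamics by construction.
* Classic two-chain R̂ cannot detect a trend shared by both chains;
  the Geweke diagnostic and split-R̂ cover that direction.
* Group comparisons are uncorrected for multiplicity, mirroring the
  analysis convention the package reproduces; the report says so
  explicitly.
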