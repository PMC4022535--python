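"""Hierarchical model: log-joint against independent oracles, sampler
correctness (grid oracle, prior recovery, parameter recovery), determinism
and shrinkage behaviour."""

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import binom, gamma, norm

from hbsdt import Valence
from hbsdt.agn_data import ConditionDataset, TrialCounts
from hbsdt.model import (
    HierParams,
    PriorConfig,
    SamplerConfig,
    derive_sigma,
    initialize_state,
    log_joint,
    log_likelihood,
    log_prior,
    sample_posterior,
)
from hbsdt.simulate import CellTruth, generate_condition


def _single_subject(H, S, F, N):
    return ConditionDataset(
        "control", Valence.POSITIVE,
        [("s1", TrialCounts(H, S - H, F, N - F))],
    )


def _oracle_log_joint(p, data, prior):
    """Direct-summation reference implementation via scipy distributions."""
    total = 0.0
    for i, (_, c) in enumerate(data.subjects):
        h = ndtr(p.d[i] / 2.0 - p.c[i])
        f = ndtr(-p.d[i] / 2.0 - p.c[i])
        total += binom.logpmf(c.hits, c.signal_total, h)
        total += binom.logpmf(c.false_alarms, c.noise_total, f)
        total += norm.logpdf(p.c[i], p.mu_c, p.lambda_c**-0.5)
        total += norm.logpdf(p.d[i], p.mu_d, p.lambda_d**-0.5)
    for mu in (p.mu_c, p.mu_d):
        total += norm.logpdf(mu, prior.mu_mean, prior.mu_precision**-0.5)
    for lam in (p.lambda_c, p.lambda_d):
        total += gamma.logpdf(lam, prior.lambda_shape, scale=1.0 / prior.lambda_rate)
    return float(total)


def _random_state(rng, n):
    return HierParams(
        c=rng.normal(0, 1, n),
        d=rng.normal(1.5, 1, n),
        mu_c=rng.normal(),
        mu_d=rng.normal(2, 1),
        lambda_c=rng.gamma(2, 2),
        lambda_d=rng.gamma(2, 2),
    )


class TestLogJoint:
    def test_chance_level_closed_form(self):
        """c=d=0 gives h=f=0.5; likelihood is two Binomial(27; 54, .5) terms."""
        data = _single_subject(27, 54, 27, 54)
        p = HierParams(np.zeros(1), np.zeros(1), 0.0, 0.0, 1.0, 1.0)
        expected = 2 * binom.logpmf(27, 54, 0.5)
        assert log_likelihood(p, data) == pytest.approx(expected, abs=1e-10)

    def test_decomposition(self, default_condition):
        data, _ = default_condition
        rng = np.random.default_rng(0)
        prior = PriorConfig()
        for _ in range(5):
            p = _random_state(rng, data.n_subjects)
            assert log_joint(p, data, prior) == pytest.approx(
                log_likelihood(p, data) + log_prior(p, prior), rel=1e-12
            )

    def test_against_direct_summation_oracle(self, default_condition):
        data, _ = default_condition
        rng = np.random.default_rng(42)
        prior = PriorConfig()
        for _ in range(20):
            p = _random_state(rng, data.n_subjects)
            assert log_joint(p, data, prior) == pytest.approx(
                _oracle_log_joint(p, data, prior), abs=1e-8
            )

    def test_nonpositive_precision_rejected_not_raised(self, default_condition):
        data, _ = default_condition
        p = HierParams(np.zeros(20), np.zeros(20), 0.0, 0.0, -1.0, 1.0)
        assert log_joint(p, data, PriorConfig()) == float("-inf")

    def test_extreme_counts_finite(self):
        """log-CDF tail stability: perfect subject, far-off parameters."""
        data = _single_subject(54, 54, 0, 54)
        p = HierParams(np.array([-8.0]), np.array([20.0]), 0.0, 0.0, 1.0, 1.0)
        assert np.isfinite(log_joint(p, data, PriorConfig()))


class TestInitialization:
    def test_matches_classical_estimates(self, default_condition):
        from hbsdt import sdt

        data, _ = default_condition
        state = initialize_state(data, PriorConfig(), np.random.default_rng(0))
        ests = [sdt.estimate(c) for _, c in data.subjects]
        assert state.c == pytest.approx([e.criterion for e in ests])
        assert state.d == pytest.approx([e.d_prime for e in ests])

    def test_degenerate_cohort_floored(self):
        data = ConditionDataset(
            "control", Valence.POSITIVE,
            [(f"s{i}", TrialCounts(40, 14, 10, 44)) for i in range(5)],
        )
        state = initialize_state(data, PriorConfig(), np.random.default_rng(0))
        assert state.lambda_c <= 100.0 + 1e-9
        assert np.isfinite(log_joint(state, data, PriorConfig()))

    def test_random_datasets_finite_log_joint(self):
        rng = np.random.default_rng(11)
        prior = PriorConfig()
        for k in range(100):
            data, _ = generate_condition(
                CellTruth(rng.normal(0, 0.7), rng.normal(1.5, 1.0), 0.4, 0.4),
                "control", Valence.POSITIVE, rng, n_subjects=5,
                missing_rate=0.01,
            )
            state = initialize_state(data, prior, rng)
            assert np.isfinite(log_joint(state, data, prior))


class TestSampler:
    def test_seed_determinism(self, default_condition, fast_sampler):
        data, _ = default_condition
        a = sample_posterior(data, PriorConfig(), fast_sampler)
        b = sample_posterior(data, PriorConfig(), fast_sampler)
        for name in ("c", "d", "mu_c", "mu_d", "lambda_c", "lambda_d"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_single_subject_matches_grid_oracle(self):
        """MCMC with fixed group parameters vs 2-D grid integration.

        The subject-level target is Bin(H; S, Phi(d/2-c)) Bin(F; N,
        Phi(-d/2-c)) N(c|0, 1000) N(d|0, 1000), integrable on a grid.
        """
        data = _single_subject(45, 54, 9, 54)
        cfg = SamplerConfig(
            n_chains=2, n_iterations=10_000, adapt_iterations=2_000, seed=3,
            fixed_group=(0.0, 0.0, 0.001, 0.001),
        )
        samples = sample_posterior(data, PriorConfig(), cfg)

        cs = np.linspace(-2.0, 2.0, 401)
        ds = np.linspace(-1.0, 6.0, 701)
        C, D = np.meshgrid(cs, ds, indexing="ij")
        h = ndtr(D / 2.0 - C)
        f = ndtr(-D / 2.0 - C)
        logpost = (
            binom.logpmf(45, 54, h)
            + binom.logpmf(9, 54, f)
            + norm.logpdf(C, 0.0, 0.001**-0.5)
            + norm.logpdf(D, 0.0, 0.001**-0.5)
        )
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        grid_mean_c = float((w * C).sum())
        grid_mean_d = float((w * D).sum())

        for name, target in (("c[s1]", grid_mean_c), ("d[s1]", grid_mean_d)):
            x = samples.flat(name)
            # batch-means Monte-Carlo standard error of the chain mean
            nb = 50
            bs = len(x) // nb
            se = np.std(x[: nb * bs].reshape(nb, bs).mean(axis=1), ddof=1) / np.sqrt(nb)
            assert abs(x.mean() - target) < 3 * se, name

    def test_prior_only_sampling_recovers_prior_moments(self):
        """With the likelihood disabled the chain targets the prior itself.

        Uses a moderately informative prior whose moments are checkable at
        Monte-Carlo scale: mu ~ N(1, 1/4), lambda ~ Gamma(3, rate 2).
        """
        data = _single_subject(27, 54, 27, 54)
        prior = PriorConfig(mu_mean=1.0, mu_precision=4.0,
                            lambda_shape=3.0, lambda_rate=2.0)
        cfg = SamplerConfig(n_chains=2, n_iterations=20_000,
                            adapt_iterations=1_000, seed=5,
                            include_likelihood=False)
        s = sample_posterior(data, prior, cfg)
        assert s.flat("mu_c").mean() == pytest.approx(1.0, abs=0.02)
        assert s.flat("mu_d").std() == pytest.approx(0.5, abs=0.02)
        assert s.flat("lambda_c").mean() == pytest.approx(1.5, abs=0.05)
        assert s.flat("lambda_d").var() == pytest.approx(0.75, abs=0.08)

    def test_recovers_group_mean_discriminability(self, default_condition):
        """Posterior mean of mu_d lies within 3 posterior SDs of truth 2.0."""
        data, _ = default_condition
        cfg = SamplerConfig(n_chains=2, n_iterations=4000,
                            adapt_iterations=1000, seed=9)
        s = sample_posterior(data, PriorConfig(), cfg)
        x = s.flat("mu_d")
        assert abs(x.mean() - 2.0) < 3 * x.std()

    def test_posterior_contraction_with_more_trials(self):
        """Doubling trials per subject shrinks the posterior SD of mu_d."""
        sds = {6: [], 12: []}
        for seed in range(5):
            for blocks in (6, 12):
                rng = np.random.default_rng(100 + seed)
                data, _ = generate_condition(
                    CellTruth(0.0, 2.0, 0.3, 0.3), "control", Valence.POSITIVE,
                    rng, n_subjects=20, missing_rate=0.0,
                    blocks_per_subject=blocks,
                )
                cfg = SamplerConfig(n_chains=2, n_iterations=1500,
                                    adapt_iterations=800, seed=seed)
                s = sample_posterior(data, PriorConfig(), cfg)
                sds[blocks].append(s.flat("mu_d").std())
        assert np.mean(sds[12]) < np.mean(sds[6])

    def test_subject_shrinkage_toward_group_mean(self, fast_sampler):
        """Partial pooling: posterior subject means lie between the classical
        estimate and the group-level posterior mean for >= 90% of subjects."""
        from hbsdt import sdt

        rng = np.random.default_rng(77)
        data, _ = generate_condition(
            CellTruth(0.3, 2.0, 0.3, 0.3), "control", Valence.POSITIVE,
            rng, n_subjects=20, missing_rate=0.0,
        )
        s = sample_posterior(data, PriorConfig(), fast_sampler)
        mu_hat = s.flat("mu_c").mean()
        # the binomial-probit likelihood is skewed, so the subject-level
        # posterior mean can sit slightly past the classical probit point
        # estimate; tolerate that O(1/trials) offset
        tol = 0.05
        inside = 0
        for i, (sid, counts) in enumerate(data.subjects):
            classical = sdt.estimate(counts).criterion
            post = s.flat(f"c[{sid}]").mean()
            lo, hi = sorted((classical, mu_hat))
            inside += lo - tol <= post <= hi + tol
        assert inside >= 18

    def test_sigma_derivation(self, default_condition, fast_sampler):
        data, _ = default_condition
        s = derive_sigma(sample_posterior(data, PriorConfig(), fast_sampler))
        assert np.allclose(s.sigma_c, s.lambda_c**-0.5)
        assert np.allclose(s.sigma_d, s.lambda_d**-0.5)
        # monotone: larger lambda => smaller sigma
        order = np.argsort(s.lambda_c.ravel())
        assert np.all(np.diff(s.sigma_c.ravel()[order]) <= 0)

    def test_simulation_based_calibration_rank_uniformity(self):
        """Rank of true mu_d among thinned posterior draws is ~uniform over
        truths drawn from a plausible box (chi-square at 0.01)."""
        from scipy.stats import chisquare

        n_rep, n_bins = 50, 10
        ranks = []
        for r in range(n_rep):
            rng = np.random.default_rng(1000 + r)
            truth = CellTruth(
                mu_c=float(rng.uniform(-0.5, 0.5)),
                mu_d=float(rng.uniform(1.0, 3.0)),
                sigma_c=0.3, sigma_d=0.3,
            )
            data, _ = generate_condition(
                truth, "control", Valence.POSITIVE, rng,
                n_subjects=10, missing_rate=0.0,
            )
            cfg = SamplerConfig(n_chains=2, n_iterations=900,
                                adapt_iterations=600, seed=2000 + r)
            s = sample_posterior(data, PriorConfig(), cfg)
            draws = s.flat("mu_d")[:: 20]  # thin to ~90 near-independent draws
            k = len(draws)
            rank = int(np.sum(draws < truth.mu_d))
            ranks.append(rank / (k + 1))
        counts, _ = np.histogram(ranks, bins=n_bins, range=(0, 1))
        _, p = chisquare(counts)
        assert p > 0.01
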