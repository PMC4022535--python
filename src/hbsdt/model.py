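"""Hierarchical Bayesian signal-detection model and its MCMC sampler.

One model is fitted per group x signal-valence cell.  For subject i with
``S_i`` signal and ``N_i`` noise trials::

    H_i ~ Binomial(S_i, Phi(d_i/2 - c_i))        hits
    F_i ~ Binomial(N_i, Phi(-d_i/2 - c_i))       false alarms
    c_i ~ Normal(mu_c, 1/lambda_c)               subject bias
    d_i ~ Normal(mu_d, 1/lambda_d)               subject discriminability
    mu_c, mu_d ~ Normal(mu_mean, 1/mu_precision)
    lambda_c, lambda_d ~ Gamma(shape, rate)

with vague defaults (precision 0.001 normals, Gamma(0.001, 0.001)) standing
in for reference priors.  Group standard deviations are the derived
``sigma = lambda**-0.5``.

The sampler is Metropolis-within-Gibbs: vectorised Gaussian random-walk
updates for the subject-level (c_i, d_i), with per-subject proposal scales
adapted toward a 20-50% acceptance rate during a discarded warm-up phase,
and conjugate Gibbs draws for the group means and precisions.  Retained
draws therefore form a valid Markov chain with the joint posterior as its
invariant distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln, log_ndtr
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from .agn_data import ConditionDataset
from . import sdt


@dataclass(frozen=True)
class PriorConfig:
    """Hyperprior settings; defaults encode the vague/reference prior."""

    mu_mean: float = 0.0
    mu_precision: float = 0.001
    lambda_shape: float = 0.001
    lambda_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.mu_precision <= 0 or self.lambda_shape <= 0 or self.lambda_rate <= 0:
            raise ValueError("precision, shape and rate must be positive")

    def narrowed(self, factor: float = 10.0) -> "PriorConfig":
        """A narrower variant for robustness checks: precisions scaled up."""
        return PriorConfig(
            mu_mean=self.mu_mean,
            mu_precision=self.mu_precision * factor,
            lambda_shape=self.lambda_shape * factor,
            lambda_rate=self.lambda_rate * factor,
        )


@dataclass
class SamplerConfig:
    """MCMC run settings.

    ``n_iterations`` draws per chain are retained after discarding
    ``burn_in`` draws; an additional ``adapt_iterations`` warm-up draws are
    always run first (and discarded) to tune proposal scales.  Per-chain
    seeds are derived as ``seed + chain_index``.
    """

    n_chains: int = 2
    n_iterations: int = 10_000
    burn_in: int = 0
    adapt_iterations: int = 2_000
    seed: int = 0
    #: Metropolis sweeps over the subject parameters per iteration; a few
    #: sweeps per Gibbs update of the group level shortens subject-chain
    #: autocorrelation times at negligible cost.
    subject_sweeps: int = 3
    include_likelihood: bool = True
    #: when set, (mu_c, mu_d, lambda_c, lambda_d) are held fixed at these
    #: values and only subject parameters are sampled (used e.g. to check
    #: the subject-level model against a 2-D grid-integration oracle).
    fixed_group: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        if self.n_chains < 2 and self.fixed_group is None:
            raise ValueError("at least two chains are required")
        if self.n_chains < 1:
            raise ValueError("at least one chain is required")
        if self.n_iterations < 1 or self.burn_in < 0 or self.adapt_iterations < 0:
            raise ValueError("iteration counts must be non-negative (draws >= 1)")


FAST_PROFILE = SamplerConfig(n_chains=2, n_iterations=2_000, adapt_iterations=1_000)


@dataclass
class HierParams:
    """One state of the model."""

    c: np.ndarray
    d: np.ndarray
    mu_c: float
    mu_d: float
    lambda_c: float
    lambda_d: float


@dataclass
class PosteriorSamples:
    """Retained draws for one fitted cell: arrays indexed (chain, draw[, subject])."""

    c: np.ndarray
    d: np.ndarray
    mu_c: np.ndarray
    mu_d: np.ndarray
    lambda_c: np.ndarray
    lambda_d: np.ndarray
    subject_ids: list[str]
    prior: PriorConfig
    config: SamplerConfig
    group: str = ""
    signal_valence: str = ""
    sigma_c: Optional[np.ndarray] = None
    sigma_d: Optional[np.ndarray] = None

    @property
    def n_chains(self) -> int:
        return self.mu_c.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu_c.shape[1]

    def group_level_names(self) -> list[str]:
        names = ["mu_c", "mu_d", "lambda_c", "lambda_d"]
        if self.sigma_c is not None:
            names += ["sigma_c", "sigma_d"]
        return names

    def parameter_names(self) -> list[str]:
        """Group-level names plus per-subject c[id] and d[id]."""
        names = self.group_level_names()
        for sid in self.subject_ids:
            names.append(f"c[{sid}]")
        for sid in self.subject_ids:
            names.append(f"d[{sid}]")
        return names

    def chains(self, name: str) -> np.ndarray:
        """Draws for one parameter as a (chains, draws) array."""
        if name.startswith(("c[", "d[")) and name.endswith("]"):
            sid = name[2:-1]
            idx = self.subject_ids.index(sid)
            return (self.c if name[0] == "c" else self.d)[:, :, idx]
        arr = getattr(self, name, None)
        if arr is None:
            raise KeyError(f"parameter {name!r} not present")
        return arr

    def flat(self, name: str) -> np.ndarray:
        """Draws for one parameter with chains concatenated."""
        return self.chains(name).reshape(-1)


def _data_arrays(data: ConditionDataset) -> tuple[np.ndarray, ...]:
    H = np.array([c.hits for _, c in data.subjects], dtype=float)
    S = np.array([c.signal_total for _, c in data.subjects], dtype=float)
    F = np.array([c.false_alarms for _, c in data.subjects], dtype=float)
    N = np.array([c.noise_total for _, c in data.subjects], dtype=float)
    return H, S, F, N


def _subject_loglik(
    c: np.ndarray, d: np.ndarray, H: np.ndarray, S: np.ndarray,
    F: np.ndarray, N: np.ndarray,
) -> np.ndarray:
    """Per-subject binomial log-likelihood, without the binomial coefficients.

    Uses ``log_ndtr`` so hit/false-alarm probabilities deep in the normal
    tails stay finite.
    """
    x = 0.5 * d - c
    y = -0.5 * d - c
    return (
        H * log_ndtr(x)
        + (S - H) * log_ndtr(-x)
        + F * log_ndtr(y)
        + (N - F) * log_ndtr(-y)
    )


def _binom_const(data: ConditionDataset) -> float:
    H, S, F, N = _data_arrays(data)
    return float(
        np.sum(gammaln(S + 1) - gammaln(H + 1) - gammaln(S - H + 1))
        + np.sum(gammaln(N + 1) - gammaln(F + 1) - gammaln(N - F + 1))
    )


def log_likelihood(p: HierParams, data: ConditionDataset) -> float:
    """Full binomial log-likelihood (including binomial coefficients)."""
    H, S, F, N = _data_arrays(data)
    return float(np.sum(_subject_loglik(p.c, p.d, H, S, F, N))) + _binom_const(data)


def log_prior(p: HierParams, prior: PriorConfig) -> float:
    """Log-density of the hierarchy above the data.

    Returns ``-inf`` (a rejected state, not an exception) for non-positive
    precisions.
    """
    if p.lambda_c <= 0 or p.lambda_d <= 0:
        return float("-inf")
    mu_sd = prior.mu_precision**-0.5
    lp = norm.logpdf(p.mu_c, prior.mu_mean, mu_sd)
    lp += norm.logpdf(p.mu_d, prior.mu_mean, mu_sd)
    lp += gamma_dist.logpdf(p.lambda_c, prior.lambda_shape, scale=1.0 / prior.lambda_rate)
    lp += gamma_dist.logpdf(p.lambda_d, prior.lambda_shape, scale=1.0 / prior.lambda_rate)
    lp += np.sum(norm.logpdf(p.c, p.mu_c, p.lambda_c**-0.5))
    lp += np.sum(norm.logpdf(p.d, p.mu_d, p.lambda_d**-0.5))
    return float(lp)


def log_joint(p: HierParams, data: ConditionDataset, prior: PriorConfig) -> float:
    """``log_likelihood + log_prior``; finite for all valid states."""
    lp = log_prior(p, prior)
    if not np.isfinite(lp):
        return lp
    return lp + log_likelihood(p, data)


def initialize_state(
    data: ConditionDataset, prior: PriorConfig, rng: np.random.Generator
) -> HierParams:
    """Start from classical per-subject estimates (extreme-rate adjusted).

    Group means are set to the sample means and precisions to inverse sample
    variances, with the variance floored at 0.01 so degenerate cohorts (all
    subjects identical) still yield a finite log-joint.
    """
    ests = [sdt.estimate(c) for _, c in data.subjects]
    c0 = np.array([e.criterion for e in ests])
    d0 = np.array([e.d_prime for e in ests])
    var_floor = 0.01
    var_c = max(float(np.var(c0)), var_floor)
    var_d = max(float(np.var(d0)), var_floor)
    return HierParams(
        c=c0,
        d=d0,
        mu_c=float(np.mean(c0)),
        mu_d=float(np.mean(d0)),
        lambda_c=1.0 / var_c,
        lambda_d=1.0 / var_d,
    )


def derive_sigma(samples: PosteriorSamples) -> PosteriorSamples:
    """Attach per-draw group SDs ``sigma = lambda**-0.5`` to the samples."""
    samples.sigma_c = samples.lambda_c**-0.5
    samples.sigma_d = samples.lambda_d**-0.5
    return samples


def _run_chain(
    data: ConditionDataset,
    prior: PriorConfig,
    cfg: SamplerConfig,
    chain_seed: int,
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(chain_seed)
    H, S, F, N = _data_arrays(data)
    n = len(H)
    state = initialize_state(data, prior, rng)
    c, d = state.c.copy(), state.d.copy()
    mu_c, mu_d = state.mu_c, state.mu_d
    lam_c, lam_d = state.lambda_c, state.lambda_d
    if cfg.fixed_group is not None:
        mu_c, mu_d, lam_c, lam_d = cfg.fixed_group

    scale_c = np.full(n, 0.3)
    scale_d = np.full(n, 0.3)
    acc_c = np.zeros(n)
    acc_d = np.zeros(n)
    shift_scale = {"c": 0.1, "d": 0.1}
    shift_acc = {"c": 0, "d": 0}
    scale_shrink = {"c": 0.5, "d": 0.5}
    shrink_acc = {"c": 0, "d": 0}
    window = 50

    include_lik = cfg.include_likelihood
    loglik = _subject_loglik(c, d, H, S, F, N) if include_lik else np.zeros(n)

    total = cfg.adapt_iterations + cfg.burn_in + cfg.n_iterations
    keep_from = cfg.adapt_iterations + cfg.burn_in
    out_c = np.empty((cfg.n_iterations, n))
    out_d = np.empty((cfg.n_iterations, n))
    out = {
        k: np.empty(cfg.n_iterations) for k in ("mu_c", "mu_d", "lambda_c", "lambda_d")
    }

    sweeps = max(int(cfg.subject_sweeps), 1)
    for t in range(total):
        for _ in range(sweeps):
            # subject bias: vectorised random-walk Metropolis
            c_prop = c + rng.standard_normal(n) * scale_c
            ll_prop = (
                _subject_loglik(c_prop, d, H, S, F, N) if include_lik else np.zeros(n)
            )
            delta = (
                ll_prop - loglik
                - 0.5 * lam_c * ((c_prop - mu_c) ** 2 - (c - mu_c) ** 2)
            )
            accept = np.log(rng.random(n)) < delta
            c = np.where(accept, c_prop, c)
            loglik = np.where(accept, ll_prop, loglik)
            acc_c += accept

            # subject discriminability
            d_prop = d + rng.standard_normal(n) * scale_d
            ll_prop = (
                _subject_loglik(c, d_prop, H, S, F, N) if include_lik else np.zeros(n)
            )
            delta = (
                ll_prop - loglik
                - 0.5 * lam_d * ((d_prop - mu_d) ** 2 - (d - mu_d) ** 2)
            )
            accept = np.log(rng.random(n)) < delta
            d = np.where(accept, d_prop, d)
            loglik = np.where(accept, ll_prop, loglik)
            acc_d += accept

        if cfg.fixed_group is None:
            # joint translation moves: shift mu and all subject values
            # together.  The subject-level Normal terms are translation
            # invariant, so this directly mixes the slow global level of
            # the centred hierarchy.
            for which in ("c", "d") * sweeps:
                delta = rng.normal(0.0, shift_scale[which])
                if which == "c":
                    vec_prop, mu_prop = c + delta, mu_c + delta
                    ll_prop = (
                        _subject_loglik(vec_prop, d, H, S, F, N)
                        if include_lik else np.zeros(n)
                    )
                    mu_cur = mu_c
                else:
                    vec_prop, mu_prop = d + delta, mu_d + delta
                    ll_prop = (
                        _subject_loglik(c, vec_prop, H, S, F, N)
                        if include_lik else np.zeros(n)
                    )
                    mu_cur = mu_d
                log_ratio = float(np.sum(ll_prop - loglik)) - 0.5 * prior.mu_precision * (
                    (mu_prop - prior.mu_mean) ** 2 - (mu_cur - prior.mu_mean) ** 2
                )
                if np.log(rng.random()) < log_ratio:
                    if which == "c":
                        c, mu_c = vec_prop, mu_prop
                    else:
                        d, mu_d = vec_prop, mu_prop
                    loglik = ll_prop
                    shift_acc[which] += 1

            # conjugate Gibbs: group means then precisions
            prec = prior.mu_precision + n * lam_c
            mean = (prior.mu_precision * prior.mu_mean + lam_c * c.sum()) / prec
            mu_c = rng.normal(mean, prec**-0.5)
            prec = prior.mu_precision + n * lam_d
            mean = (prior.mu_precision * prior.mu_mean + lam_d * d.sum()) / prec
            mu_d = rng.normal(mean, prec**-0.5)
            lam_c = rng.gamma(
                prior.lambda_shape + 0.5 * n,
                1.0 / (prior.lambda_rate + 0.5 * np.sum((c - mu_c) ** 2)),
            )
            lam_d = rng.gamma(
                prior.lambda_shape + 0.5 * n,
                1.0 / (prior.lambda_rate + 0.5 * np.sum((d - mu_d) ** 2)),
            )

            # non-centred scale moves: MH on log(lambda) that jointly
            # rescales the subject deviations, mixing the variance funnel.
            # With u_i = sqrt(lambda) (x_i - mu) held fixed the Normal terms
            # and Jacobians cancel, leaving likelihood x Gamma(lambda) x
            # lambda in the ratio.  Repeated a few times per iteration: the
            # funnel is the slowest direction of this posterior.
            for which in ("c", "d") * sweeps:
                eps = rng.normal(0.0, scale_shrink[which])
                shrink = np.exp(-0.5 * eps)
                if which == "c":
                    lam_prop = lam_c * np.exp(eps)
                    vec_prop = mu_c + (c - mu_c) * shrink
                    ll_prop = (
                        _subject_loglik(vec_prop, d, H, S, F, N)
                        if include_lik else np.zeros(n)
                    )
                    lam_cur = lam_c
                else:
                    lam_prop = lam_d * np.exp(eps)
                    vec_prop = mu_d + (d - mu_d) * shrink
                    ll_prop = (
                        _subject_loglik(c, vec_prop, H, S, F, N)
                        if include_lik else np.zeros(n)
                    )
                    lam_cur = lam_d
                log_ratio = (
                    float(np.sum(ll_prop - loglik))
                    + prior.lambda_shape * eps
                    - prior.lambda_rate * (lam_prop - lam_cur)
                )
                if np.log(rng.random()) < log_ratio:
                    if which == "c":
                        c, lam_c = vec_prop, lam_prop
                    else:
                        d, lam_d = vec_prop, lam_prop
                    loglik = ll_prop
                    shrink_acc[which] += 1

        # proposal adaptation, warm-up only
        if t < cfg.adapt_iterations and (t + 1) % window == 0:
            rate_c = acc_c / (window * sweeps)
            rate_d = acc_d / (window * sweeps)
            scale_c *= np.where(rate_c < 0.2, 0.7, np.where(rate_c > 0.5, 1.4, 1.0))
            scale_d *= np.where(rate_d < 0.2, 0.7, np.where(rate_d > 0.5, 1.4, 1.0))
            acc_c[:] = 0.0
            acc_d[:] = 0.0
            for which in ("c", "d"):
                rate = shift_acc[which] / (window * sweeps)
                if rate < 0.2:
                    shift_scale[which] *= 0.7
                elif rate > 0.5:
                    shift_scale[which] *= 1.4
                shift_acc[which] = 0
                rate = shrink_acc[which] / (window * sweeps)
                if rate < 0.2:
                    scale_shrink[which] *= 0.7
                elif rate > 0.5:
                    scale_shrink[which] *= 1.4
                shrink_acc[which] = 0

        if t >= keep_from:
            i = t - keep_from
            out_c[i] = c
            out_d[i] = d
            out["mu_c"][i] = mu_c
            out["mu_d"][i] = mu_d
            out["lambda_c"][i] = lam_c
            out["lambda_d"][i] = lam_d

    out["c"] = out_c
    out["d"] = out_d
    return out


def sample_posterior(
    data: ConditionDataset, prior: PriorConfig, cfg: SamplerConfig
) -> PosteriorSamples:
    """Draw from the joint posterior for one condition dataset.

    Runs ``cfg.n_chains`` independent chains (seeds ``cfg.seed + chain``),
    each retaining ``cfg.n_iterations`` draws after the warm-up and burn-in
    phases are discarded.  Deterministic given the configuration.
    """
    chains = [
        _run_chain(data, prior, cfg, cfg.seed + k) for k in range(cfg.n_chains)
    ]
    stack = lambda key: np.stack([ch[key] for ch in chains])
    return PosteriorSamples(
        c=stack("c"),
        d=stack("d"),
        mu_c=stack("mu_c"),
        mu_d=stack("mu_d"),
        lambda_c=stack("lambda_c"),
        lambda_d=stack("lambda_d"),
        subject_ids=list(data.subject_ids),
        prior=prior,
        config=cfg,
        group=data.group,
        signal_valence=str(data.signal_valence.value),
    )
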