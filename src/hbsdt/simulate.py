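"""Synthetic AGN study generator.

Generates block-structured go/no-go datasets with the statistical structure
the hierarchical model assumes: per group x signal-valence cell, subject
parameters ``c_i ~ N(mu_c, sigma_c^2)`` and ``d_i ~ N(mu_d, sigma_d^2)``,
and per block binomial hit / false-alarm counts with success probabilities
``Phi(d_i/2 - c_i)`` and ``Phi(-d_i/2 - c_i)`` over nine signal and nine
noise trials.  Occasional missing trials are modelled as independent
uniform dropout before the binomial draw, emulating the small per-group
shortfalls seen in published aggregate totals.

Default design constants match the study conditions being emulated: three
groups of 20 subjects, 18 scored blocks each (six per signal valence), and
subject parameters drawn independently per condition (conditions are
modelled separately downstream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from .agn_data import (
    GROUPS,
    REFERENCE_RATES,
    BlockRecord,
    ConditionDataset,
    SubjectRecord,
    TrialCounts,
    Valence,
    block_schedule,
    TRIALS_PER_BLOCK,
)
from . import sdt


@dataclass(frozen=True)
class CellTruth:
    """Ground-truth group parameters for one group x valence cell."""

    mu_c: float
    mu_d: float
    sigma_c: float = 0.3
    sigma_d: float = 0.3

    def __post_init__(self) -> None:
        if self.sigma_c < 0 or self.sigma_d < 0:
            raise ValueError("sigmas must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth plus design constants for a whole synthetic study."""

    cells: Mapping[tuple[str, Valence], CellTruth]
    n_subjects: int = 20
    missing_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 0.05:
            raise ValueError("missing_rate must lie in [0, 0.05]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class GeneratedStudy:
    subjects: list[SubjectRecord]
    truth: SyntheticTruth
    #: latent (c_i, d_i) per (group, valence, subject_id), for recovery tests
    latents: dict[tuple[str, str, str], tuple[float, float]]


def _draw_block_counts(
    rng: np.random.Generator, h: float, f: float, missing_rate: float
) -> TrialCounts:
    s_kept = int(rng.binomial(TRIALS_PER_BLOCK, 1.0 - missing_rate)) \
        if missing_rate > 0 else TRIALS_PER_BLOCK
    n_kept = int(rng.binomial(TRIALS_PER_BLOCK, 1.0 - missing_rate)) \
        if missing_rate > 0 else TRIALS_PER_BLOCK
    hits = int(rng.binomial(s_kept, h)) if s_kept else 0
    fas = int(rng.binomial(n_kept, f)) if n_kept else 0
    return TrialCounts(hits, s_kept - hits, fas, n_kept - fas)


def generate_condition(
    truth: CellTruth,
    group: str,
    valence: Valence,
    rng: np.random.Generator,
    n_subjects: int = 20,
    missing_rate: float = 0.001,
    blocks_per_subject: int = 6,
) -> tuple[ConditionDataset, dict[str, tuple[float, float]]]:
    """Generate one condition dataset directly (no block schedule bookkeeping).

    Returns the dataset plus the latent (c_i, d_i) per subject.
    ``blocks_per_subject`` can be raised to study the many-trials limit.
    """
    subjects: list[tuple[str, TrialCounts]] = []
    latents: dict[str, tuple[float, float]] = {}
    for i in range(n_subjects):
        sid = f"{group[:3]}{i + 1:03d}"
        c_i = float(rng.normal(truth.mu_c, truth.sigma_c))
        d_i = float(rng.normal(truth.mu_d, truth.sigma_d))
        h, f = sdt.rates_from_sdt(c_i, d_i)
        total = TrialCounts(0, 0, 0, 0)
        for _ in range(blocks_per_subject):
            total = total + _draw_block_counts(rng, h, f, missing_rate)
        subjects.append((sid, total))
        latents[sid] = (c_i, d_i)
    return (
        ConditionDataset(group=group, signal_valence=valence, subjects=subjects),
        latents,
    )


def generate_study(truth: SyntheticTruth, seed: Optional[int] = None) -> GeneratedStudy:
    """Generate complete subject records for all groups and valences.

    Each subject's (c_i, d_i) are drawn independently per signal valence,
    matching the separate per-condition models fitted downstream; the 18
    scored blocks follow the fixed administration schedule.
    """
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    schedule = block_schedule()
    subjects: list[SubjectRecord] = []
    latents: dict[tuple[str, str, str], tuple[float, float]] = {}
    for group in GROUPS:
        for i in range(truth.n_subjects):
            sid = f"{group[:3]}{i + 1:03d}"
            # one latent (c, d) and hence one rate pair per signal valence
            rates: dict[Valence, tuple[float, float]] = {}
            for valence in Valence:
                cell = truth.cells[(group, valence)]
                c_i = float(rng.normal(cell.mu_c, cell.sigma_c))
                d_i = float(rng.normal(cell.mu_d, cell.sigma_d))
                rates[valence] = sdt.rates_from_sdt(c_i, d_i)
                latents[(group, valence.value, sid)] = (c_i, d_i)
            blocks = []
            for idx, (sig, noise) in enumerate(schedule, start=1):
                h, f = rates[sig]
                blocks.append(
                    BlockRecord(
                        block_index=idx,
                        signal_valence=sig,
                        noise_valence=noise,
                        counts=_draw_block_counts(rng, h, f, truth.missing_rate),
                    )
                )
            subjects.append(SubjectRecord(subject_id=sid, group=group, blocks=blocks))
    return GeneratedStudy(subjects=subjects, truth=truth, latents=latents)


def uniform_truth(
    mu_c: float = 0.0,
    mu_d: float = 2.0,
    sigma_c: float = 0.3,
    sigma_d: float = 0.3,
    n_subjects: int = 20,
    missing_rate: float = 0.001,
    seed: int = 0,
) -> SyntheticTruth:
    """The same truth in every group x valence cell (null-difference study)."""
    cell = CellTruth(mu_c, mu_d, sigma_c, sigma_d)
    cells = {(g, v): cell for g in GROUPS for v in Valence}
    return SyntheticTruth(cells=cells, n_subjects=n_subjects,
                          missing_rate=missing_rate, seed=seed)


def reference_truth(
    sigma_c: float = 0.3, sigma_d: float = 0.3, seed: int = 0
) -> SyntheticTruth:
    """Truth calibrated to the published aggregate rate table.

    Each cell's (mu_c, mu_d) are the classical criterion and d-prime of the
    published 2-dp hit/false-alarm rates for that group x valence, so that
    generated group aggregates approximate the published table up to
    binomial and subject-mixture noise.  Group SDs default to 0.3, a
    conventional value (the study reports only posterior SD contrasts, not
    the SDs themselves); missing_rate 0.001 reproduces the scale of the
    published totals' shortfall (a few trials per 1,080).
    """
    cells = {}
    for (group, valence), (h, f, _dp) in REFERENCE_RATES.items():
        r = sdt.RatePair(h, f)
        cells[(group, valence)] = CellTruth(
            mu_c=sdt.criterion(r), mu_d=sdt.dprime(r),
            sigma_c=sigma_c, sigma_d=sigma_d,
        )
    return SyntheticTruth(cells=cells, seed=seed)


def write_truth(study: GeneratedStudy, path: Union[str, Path]) -> None:
    """Write ground truth and latents as JSON for recovery testing."""
    payload = {
        "n_subjects": study.truth.n_subjects,
        "missing_rate": study.truth.missing_rate,
        "seed": study.truth.seed,
        "cells": {
            f"{g}/{v.value}": {
                "mu_c": t.mu_c, "mu_d": t.mu_d,
                "sigma_c": t.sigma_c, "sigma_d": t.sigma_d,
            }
            for (g, v), t in study.truth.cells.items()
        },
        "latents": {
            f"{g}/{v}/{sid}": {"c": c, "d": d}
            for (g, v, sid), (c, d) in study.latents.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
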