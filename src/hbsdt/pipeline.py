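"""End-to-end analysis orchestration.

``run_full_analysis`` takes a block-level dataset (from file or the
synthetic generator), fits the hierarchical model independently per group x
signal-valence cell, attaches convergence diagnostics, computes all
pairwise group comparisons of the group-level parameters, and assembles an
:class:`AnalysisReport` with full provenance.  ``run_sensitivity`` re-runs
the analysis under narrower priors and with noise conditions unpooled, and
tabulates which significant comparisons are kept, lost or gained.
"""

from __future__ import annotations

import csv
import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

from .agn_data import (
    GROUPS,
    ConditionDataset,
    SubjectRecord,
    Valence,
    aggregate_group,
    build_condition_dataset,
    read_subject_blocks,
)
from .diagnostics import ConvergenceReport, convergence_report
from .inference import compare_groups, posterior_summary
from .model import (
    PosteriorSamples,
    PriorConfig,
    SamplerConfig,
    derive_sigma,
    sample_posterior,
)

GROUP_LEVEL_PARAMS = ("mu_c", "mu_d", "sigma_c", "sigma_d")

#: Default per-valence burn-in overrides: the positive condition gets a
#: 5,000-draw burn-in (the remedy applied when early/late segment means of
#: positive-condition chains disagree).
DEFAULT_BURN_IN_OVERRIDES = {"positive": 5000}


@dataclass
class RunConfig:
    """Settings for one full analysis run."""

    input_csv: Optional[Union[str, Path]] = None
    groups: Sequence[str] = GROUPS
    conditions: Sequence[Valence] = tuple(Valence)
    pooling: Union[str, tuple[str, Valence]] = "pooled"
    prior: PriorConfig = field(default_factory=PriorConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    burn_in_overrides: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BURN_IN_OVERRIDES)
    )
    seed: int = 0

    def sampler_for(self, valence: Valence) -> SamplerConfig:
        burn = self.burn_in_overrides.get(valence.value, self.sampler.burn_in)
        return replace(self.sampler, burn_in=burn)


@dataclass
class CellResult:
    group: str
    valence: Valence
    samples: PosteriorSamples
    summaries: dict[str, dict]
    convergence: ConvergenceReport
    aggregate: tuple[int, int, int, int]


@dataclass
class AnalysisReport:
    cells: dict[tuple[str, str], CellResult]
    comparisons: list[dict]
    provenance: dict
    notes: list[str]

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "notes": self.notes,
            "cells": {
                f"{g}/{v}": {
                    "aggregate": list(cell.aggregate),
                    "summaries": cell.summaries,
                    "convergence": cell.convergence.to_dict(),
                }
                for (g, v), cell in self.cells.items()
            },
            "comparisons": self.comparisons,
        }

    def significant_keys(self) -> set[tuple[str, str, str, str]]:
        return {
            (c["condition"], c["parameter"], c["group_a"], c["group_b"])
            for c in self.comparisons
            if c["significant"]
        }

    def write(self, outdir: Union[str, Path]) -> None:
        """Write draws, comparisons, report and manifest under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (g, v), cell in self.cells.items():
            with (outdir / f"draws_{g}_{v}.csv").open("w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["chain", "iteration", "parameter", "value"])
                s = cell.samples
                for name in s.group_level_names():
                    arr = s.chains(name)
                    for k in range(arr.shape[0]):
                        for i, val in enumerate(arr[k]):
                            writer.writerow([k, i, name, repr(float(val))])
        with (outdir / "comparisons.csv").open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["condition", "parameter", "group_a", "group_b",
                 "hpdd_lower", "hpdd_upper", "significant"]
            )
            for c in self.comparisons:
                writer.writerow(
                    [c["condition"], c["parameter"], c["group_a"], c["group_b"],
                     repr(c["hpdd_lower"]), repr(c["hpdd_upper"]), c["significant"]]
                )
        (outdir / "report.json").write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )
        (outdir / "manifest.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True), encoding="utf-8"
        )


def _digest_subjects(subjects: Sequence[SubjectRecord]) -> str:
    h = hashlib.sha256()
    for s in sorted(subjects, key=lambda s: s.subject_id):
        for b in sorted(s.blocks, key=lambda b: b.block_index):
            h.update(
                f"{s.subject_id},{s.group},{b.block_index},"
                f"{b.signal_valence.value},{b.noise_valence.value},"
                f"{b.counts.as_tuple()}".encode()
            )
    return h.hexdigest()


def fit_cell(
    dataset: ConditionDataset, prior: PriorConfig, sampler: SamplerConfig
) -> CellResult:
    """Fit one cell: sample, derive sigmas, summarise, diagnose."""
    samples = derive_sigma(sample_posterior(dataset, prior, sampler))
    summaries = {p: posterior_summary(samples, p) for p in GROUP_LEVEL_PARAMS}
    report = convergence_report(samples)
    return CellResult(
        group=dataset.group,
        valence=dataset.signal_valence,
        samples=samples,
        summaries=summaries,
        convergence=report,
        aggregate=aggregate_group(dataset).as_tuple(),
    )


def run_full_analysis(
    cfg: RunConfig, subjects: Optional[Sequence[SubjectRecord]] = None
) -> AnalysisReport:
    """Fit every group x condition cell and compare all group pairs.

    Comparisons cover the four group-level parameters (mu_c, mu_d, sigma_c,
    sigma_d) for every unordered group pair within each condition, using
    the 95% HPD of the paired draw-wise difference; significance is the
    zero-exclusion rule, reported uncorrected for multiplicity.
    """
    if subjects is None:
        if cfg.input_csv is None:
            raise ValueError("either subjects or cfg.input_csv is required")
        subjects = read_subject_blocks(cfg.input_csv)
    cells: dict[tuple[str, str], CellResult] = {}
    skipped: list[str] = []
    for valence in cfg.conditions:
        sampler = cfg.sampler_for(valence)
        for group in cfg.groups:
            try:
                dataset = build_condition_dataset(
                    subjects, group, valence, pooling=cfg.pooling
                )
            except Exception as exc:
                warnings.warn(f"skipping {group}/{valence.value}: {exc}", stacklevel=2)
                skipped.append(f"{group}/{valence.value}")
                continue
            cells[(group, valence.value)] = fit_cell(dataset, cfg.prior, sampler)
    comparisons: list[dict] = []
    for valence in cfg.conditions:
        fitted = [g for g in cfg.groups if (g, valence.value) in cells]
        for ga, gb in itertools.combinations(fitted, 2):
            for param in GROUP_LEVEL_PARAMS:
                comp = compare_groups(
                    cells[(ga, valence.value)].samples,
                    cells[(gb, valence.value)].samples,
                    param,
                )
                comparisons.append(
                    {
                        "condition": valence.value,
                        "parameter": param,
                        "group_a": ga,
                        "group_b": gb,
                        "hpdd_lower": comp.hpdd.lower,
                        "hpdd_upper": comp.hpdd.upper,
                        "mean_difference": comp.mean_difference,
                        "significant": comp.significant,
                    }
                )
    convergence_ok = all(c.convergence.rhat_pass for c in cells.values())
    provenance = {
        "prior": vars(cfg.prior).copy() if hasattr(cfg.prior, "__dict__")
        else {
            "mu_mean": cfg.prior.mu_mean,
            "mu_precision": cfg.prior.mu_precision,
            "lambda_shape": cfg.prior.lambda_shape,
            "lambda_rate": cfg.prior.lambda_rate,
        },
        "sampler": {
            "n_chains": cfg.sampler.n_chains,
            "n_iterations": cfg.sampler.n_iterations,
            "burn_in": cfg.sampler.burn_in,
            "adapt_iterations": cfg.sampler.adapt_iterations,
            "seed": cfg.sampler.seed,
        },
        "burn_in_overrides": dict(cfg.burn_in_overrides),
        "pooling": str(cfg.pooling),
        "data_digest": _digest_subjects(subjects),
        "convergence_ok": convergence_ok,
        "skipped_cells": skipped,
    }
    notes = [
        "Significance is the 95% HPD zero-exclusion rule applied per comparison, "
        "uncorrected for multiple comparisons."
    ]
    if not convergence_ok:
        notes.append("WARNING: R-hat >= 1.1 for at least one fitted cell.")
    return AnalysisReport(
        cells=cells, comparisons=comparisons, provenance=provenance, notes=notes
    )


@dataclass
class SensitivityResult:
    base: AnalysisReport
    variants: dict[str, AnalysisReport]
    stability: list[dict]


def run_sensitivity(
    cfg: RunConfig,
    subjects: Optional[Sequence[SubjectRecord]] = None,
    base: Optional[AnalysisReport] = None,
    narrow_factor: float = 10.0,
    include_by_noise: bool = True,
) -> SensitivityResult:
    """Robustness re-runs: narrower priors and unpooled noise conditions.

    Unpooling halves each subject's trial count per cell (~27 signal and
    ~27 noise trials), so some effects are expected to weaken; the
    stability table lists each base-or-variant significant comparison as
    kept, lost or gained.
    """
    if subjects is None and cfg.input_csv is not None:
        subjects = read_subject_blocks(cfg.input_csv)
    if base is None:
        base = run_full_analysis(cfg, subjects)
    variants: dict[str, AnalysisReport] = {}
    narrow_cfg = replace(cfg, prior=cfg.prior.narrowed(narrow_factor))
    variants["narrow_priors"] = run_full_analysis(narrow_cfg, subjects)
    if include_by_noise:
        for noise_v in Valence:
            by_cfg = replace(cfg, pooling=("by_noise", noise_v))
            # only conditions for which this noise valence is legal
            by_cfg = replace(
                by_cfg, conditions=[v for v in cfg.conditions if v != noise_v]
            )
            variants[f"by_noise_{noise_v.value}"] = run_full_analysis(by_cfg, subjects)
    stability: list[dict] = []
    base_sig = base.significant_keys()
    for name, rep in variants.items():
        var_sig = rep.significant_keys()
        for key in sorted(base_sig | var_sig):
            status = (
                "kept" if key in base_sig and key in var_sig
                else "lost" if key in base_sig
                else "gained"
            )
            stability.append(
                {
                    "variant": name,
                    "condition": key[0],
                    "parameter": key[1],
                    "group_a": key[2],
                    "group_b": key[3],
                    "status": status,
                }
            )
    return SensitivityResult(base=base, variants=variants, stability=stability)
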