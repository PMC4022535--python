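"""Data model and I/O for affective go/no-go (AGN) block counts.

The AGN task presents blocks of emotional words; within a scored block one
valence (positive, negative or neutral) is the *signal* category (respond)
and another is the *noise* category (withhold).  Each scored block contains
nine signal and nine noise trials, and the 18 scored blocks cycle through
the six legal signal/noise pairings three times.  The analysis unit is the
per-subject count of hits, misses, false alarms and correct rejections,
pooled over blocks of a given signal valence.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union


class Valence(str, Enum):
    """Emotional word category; the closed set used by the task."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEUTRAL = "neutral"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical diagnostic group labels, in reporting order.
GROUPS = ("melancholic", "non_melancholic", "control")

#: Signal (and noise) trials per scored block.
TRIALS_PER_BLOCK = 9

#: Scored blocks per subject (two training blocks are never represented).
N_SCORED_BLOCKS = 18


class ValidationError(ValueError):
    """Raised when task data violate the block/count invariants."""


class ParseError(ValueError):
    """Raised when a delimited input file cannot be parsed."""


@dataclass(frozen=True)
class TrialCounts:
    """Hit/miss/false-alarm/correct-rejection counts for one analysis cell."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")

    @property
    def signal_total(self) -> int:
        return self.hits + self.misses

    @property
    def noise_total(self) -> int:
        return self.false_alarms + self.correct_rejections

    def __add__(self, other: "TrialCounts") -> "TrialCounts":
        return TrialCounts(
            self.hits + other.hits,
            self.misses + other.misses,
            self.false_alarms + other.false_alarms,
            self.correct_rejections + other.correct_rejections,
        )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.hits, self.misses, self.false_alarms, self.correct_rejections)


#: The six legal (signal, noise) pairings in administration order.
_SCHEDULE_CYCLE: tuple[tuple[Valence, Valence], ...] = (
    (Valence.POSITIVE, Valence.NEUTRAL),
    (Valence.POSITIVE, Valence.NEGATIVE),
    (Valence.NEUTRAL, Valence.POSITIVE),
    (Valence.NEUTRAL, Valence.NEGATIVE),
    (Valence.NEGATIVE, Valence.NEUTRAL),
    (Valence.NEGATIVE, Valence.POSITIVE),
)

LEGAL_PAIRS = frozenset(_SCHEDULE_CYCLE)


def block_schedule() -> list[tuple[Valence, Valence]]:
    """Return the 18 (signal_valence, noise_valence) pairs in administration order.

    The six legal pairings are administered in a fixed cycle repeated three
    times; no two consecutive blocks share a pairing.
    """
    return list(_SCHEDULE_CYCLE) * 3


@dataclass(frozen=True)
class BlockRecord:
    """Counts for one scored block (index 1-18)."""

    block_index: int
    signal_valence: Valence
    noise_valence: Valence
    counts: TrialCounts

    def __post_init__(self) -> None:
        if not 1 <= self.block_index <= N_SCORED_BLOCKS:
            raise ValidationError(
                f"block_index must be in 1..{N_SCORED_BLOCKS}, got {self.block_index}"
            )
        if (self.signal_valence, self.noise_valence) not in LEGAL_PAIRS:
            raise ValidationError(
                f"illegal signal/noise pair "
                f"({self.signal_valence.value}, {self.noise_valence.value})"
            )
        if self.counts.signal_total > TRIALS_PER_BLOCK:
            raise ValidationError(
                f"block {self.block_index}: hits+misses = "
                f"{self.counts.signal_total} exceeds {TRIALS_PER_BLOCK} signal trials"
            )
        if self.counts.noise_total > TRIALS_PER_BLOCK:
            raise ValidationError(
                f"block {self.block_index}: false_alarms+correct_rejections = "
                f"{self.counts.noise_total} exceeds {TRIALS_PER_BLOCK} noise trials"
            )


@dataclass
class SubjectRecord:
    """All scored blocks for one participant."""

    subject_id: str
    group: str
    blocks: list[BlockRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.blocks) > N_SCORED_BLOCKS:
            raise ValidationError(
                f"subject {self.subject_id}: more than {N_SCORED_BLOCKS} blocks"
            )
        seen = set()
        for b in self.blocks:
            if b.block_index in seen:
                raise ValidationError(
                    f"subject {self.subject_id}: duplicate block_index {b.block_index}"
                )
            seen.add(b.block_index)


@dataclass
class ConditionDataset:
    """Per-subject pooled counts for one group x signal-valence cell.

    This is the unit the hierarchical model fits: every subject contributes
    a hit count out of ``signal_total`` and a false-alarm count out of
    ``noise_total``, both of which must be at least 1.
    """

    group: str
    signal_valence: Valence
    subjects: list[tuple[str, TrialCounts]]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValidationError("ConditionDataset requires at least one subject")
        for sid, c in self.subjects:
            if c.signal_total < 1 or c.noise_total < 1:
                raise ValidationError(
                    f"subject {sid}: zero signal or noise trials in condition "
                    f"{self.signal_valence.value}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [sid for sid, _ in self.subjects]


_CSV_COLUMNS = (
    "subject_id",
    "group",
    "block_index",
    "signal_valence",
    "noise_valence",
    "hits",
    "misses",
    "false_alarms",
    "correct_rejections",
)


def _parse_valence(label: str, lineno: int) -> Valence:
    try:
        return Valence(label)
    except ValueError:
        raise ValidationError(
            f"line {lineno}: unknown valence label {label!r}"
        ) from None


def read_subject_blocks(path: Union[str, Path]) -> list[SubjectRecord]:
    """Read a block-level CSV into a list of :class:`SubjectRecord`.

    The file must carry the header columns ``subject_id, group, block_index,
    signal_valence, noise_valence, hits, misses, false_alarms,
    correct_rejections``.  Rows are validated against the block invariants;
    errors name the offending line.
    """
    path = Path(path)
    rows: dict[str, dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_CSV_COLUMNS) - set(reader.fieldnames):
            missing = set(_CSV_COLUMNS) - set(reader.fieldnames or ())
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                sid = row["subject_id"].strip()
                group = row["group"].strip()
                idx = int(row["block_index"])
                counts = TrialCounts(
                    int(row["hits"]),
                    int(row["misses"]),
                    int(row["false_alarms"]),
                    int(row["correct_rejections"]),
                )
            except (TypeError, KeyError, AttributeError) as exc:
                raise ParseError(f"{path}: malformed row at line {lineno}: {exc}") from None
            except ValueError as exc:
                raise ParseError(f"{path}: malformed row at line {lineno}: {exc}") from None
            if not sid:
                raise ParseError(f"{path}: empty subject_id at line {lineno}")
            if group not in GROUPS:
                raise ValidationError(f"line {lineno}: unknown group label {group!r}")
            block = BlockRecord(
                block_index=idx,
                signal_valence=_parse_valence(row["signal_valence"].strip(), lineno),
                noise_valence=_parse_valence(row["noise_valence"].strip(), lineno),
                counts=counts,
            )
            entry = rows.setdefault(sid, {"group": group, "blocks": {}})
            if entry["group"] != group:
                raise ValidationError(
                    f"line {lineno}: subject {sid} assigned to multiple groups"
                )
            if idx in entry["blocks"]:
                raise ValidationError(
                    f"line {lineno}: duplicate block_index {idx} for subject {sid}"
                )
            entry["blocks"][idx] = block
    return [
        SubjectRecord(
            subject_id=sid,
            group=entry["group"],
            blocks=[entry["blocks"][k] for k in sorted(entry["blocks"])],
        )
        for sid, entry in rows.items()
    ]


def write_subject_blocks(subjects: Iterable[SubjectRecord], path: Union[str, Path]) -> None:
    """Write subjects to the block-level CSV dialect read by
    :func:`read_subject_blocks`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for s in subjects:
            for b in sorted(s.blocks, key=lambda b: b.block_index):
                writer.writerow(
                    [
                        s.subject_id,
                        s.group,
                        b.block_index,
                        b.signal_valence.value,
                        b.noise_valence.value,
                        *b.counts.as_tuple(),
                    ]
                )


def pool_noise(subject: SubjectRecord, signal_valence: Valence) -> TrialCounts:
    """Sum counts over all blocks with the given signal valence.

    Both noise valences are combined, mirroring the pooled analysis in which
    e.g. the positive signal condition draws its noise trials from both the
    negative and neutral categories.
    """
    matched = [b.counts for b in subject.blocks if b.signal_valence == signal_valence]
    if not matched:
        raise ValidationError(
            f"subject {subject.subject_id}: no blocks with signal valence "
            f"{signal_valence.value}"
        )
    total = matched[0]
    for c in matched[1:]:
        total = total + c
    return total


def split_by_noise(
    subject: SubjectRecord, signal_valence: Valence
) -> dict[Valence, TrialCounts]:
    """Per-noise-valence sums for one signal valence (the unpooled view)."""
    out: dict[Valence, TrialCounts] = {}
    for b in subject.blocks:
        if b.signal_valence != signal_valence:
            continue
        if b.noise_valence in out:
            out[b.noise_valence] = out[b.noise_valence] + b.counts
        else:
            out[b.noise_valence] = b.counts
    if not out:
        raise ValidationError(
            f"subject {subject.subject_id}: no blocks with signal valence "
            f"{signal_valence.value}"
        )
    return out


def build_condition_dataset(
    subjects: Sequence[SubjectRecord],
    group: str,
    signal_valence: Valence,
    pooling: Union[str, tuple[str, Valence]] = "pooled",
) -> ConditionDataset:
    """Assemble the per-subject counts the model fits for one cell.

    ``pooling`` is either ``"pooled"`` (combine both noise valences) or
    ``("by_noise", v)`` to keep only blocks whose noise valence is ``v``.
    Subjects lacking usable trials in the cell are excluded with a warning:
    a binomial likelihood is undefined on zero totals.
    """
    members = [s for s in subjects if s.group == group]
    if not members:
        raise ValidationError(f"no subjects in group {group!r}")
    entries: list[tuple[str, TrialCounts]] = []
    for s in members:
        try:
            if pooling == "pooled":
                counts = pool_noise(s, signal_valence)
            else:
                mode, noise_v = pooling
                if mode != "by_noise":
                    raise ValueError(f"unknown pooling mode {pooling!r}")
                counts = split_by_noise(s, signal_valence).get(noise_v)
                if counts is None:
                    raise ValidationError(
                        f"subject {s.subject_id}: no {signal_valence.value} blocks "
                        f"with noise {noise_v.value}"
                    )
        except ValidationError as exc:
            warnings.warn(f"excluding subject: {exc}", stacklevel=2)
            continue
        if counts.signal_total < 1 or counts.noise_total < 1:
            warnings.warn(
                f"excluding subject {s.subject_id}: zero signal or noise total in "
                f"{signal_valence.value}",
                stacklevel=2,
            )
            continue
        entries.append((s.subject_id, counts))
    if not entries:
        raise ValidationError(
            f"no usable subjects for {group} / {signal_valence.value}"
        )
    return ConditionDataset(group=group, signal_valence=signal_valence, subjects=entries)


def aggregate_group(dataset: ConditionDataset) -> TrialCounts:
    """Component-wise sum over all subjects in the cell (group totals)."""
    total = dataset.subjects[0][1]
    for _, c in dataset.subjects[1:]:
        total = total + c
    return total


def write_aggregate_table(
    subjects: Sequence[SubjectRecord],
    path: Union[str, Path],
    groups: Sequence[str] = GROUPS,
    round_2dp: bool = True,
) -> None:
    """Write the group x valence aggregate table (counts, rates, d-prime) as CSV."""
    from . import sdt  # local import: sdt type-checks against this module

    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["group", "valence", "H", "M", "FA", "CR", "hit_rate", "fa_rate", "d_prime"]
        )
        for valence in (Valence.POSITIVE, Valence.NEGATIVE, Valence.NEUTRAL):
            for group in groups:
                ds = build_condition_dataset(subjects, group, valence)
                total = aggregate_group(ds)
                rates = sdt.rates_from_counts(total, round_2dp=round_2dp)
                dp = sdt.dprime(rates)
                if round_2dp:
                    dp = sdt.round_half_away(dp, 2)
                writer.writerow(
                    [group, valence.value, *total.as_tuple(), rates.hit_rate,
                     rates.fa_rate, dp]
                )


# ---------------------------------------------------------------------------
# Published reference aggregates
# ---------------------------------------------------------------------------

#: Group-level aggregate counts (H, M, FA, CR) published for the three-group
#: melancholia AGN study that this package models: 20 subjects per group,
#: up to 1,080 signal and 1,080 noise trials per cell (small shortfalls
#: reflect missing trials).
REFERENCE_AGGREGATES: Mapping[tuple[str, Valence], TrialCounts] = {
    ("melancholic", Valence.POSITIVE): TrialCounts(911, 169, 100, 979),
    ("non_melancholic", Valence.POSITIVE): TrialCounts(979, 101, 141, 939),
    ("control", Valence.POSITIVE): TrialCounts(964, 115, 134, 945),
    ("melancholic", Valence.NEGATIVE): TrialCounts(1007, 71, 88, 991),
    ("non_melancholic", Valence.NEGATIVE): TrialCounts(1041, 39, 72, 1007),
    ("control", Valence.NEGATIVE): TrialCounts(1008, 70, 83, 997),
    ("melancholic", Valence.NEUTRAL): TrialCounts(809, 271, 213, 864),
    ("non_melancholic", Valence.NEUTRAL): TrialCounts(861, 216, 221, 858),
    ("control", Valence.NEUTRAL): TrialCounts(908, 171, 177, 903),
}

#: The published 2-dp hit/false-alarm rates and d-prime for the same cells.
#: The study's d-prime column follows from probit-differencing these printed
#: rates (8/9 cells exactly; melancholic/positive prints the value from
#: unrounded rates, a 0.01 difference).  Three printed rate values differ by
#: 0.01 from what the printed counts imply, because the study derived its
#: rates before pooling subjects.
REFERENCE_RATES: Mapping[tuple[str, Valence], tuple[float, float, float]] = {
    ("melancholic", Valence.POSITIVE): (0.84, 0.09, 2.33),
    ("non_melancholic", Valence.POSITIVE): (0.91, 0.13, 2.47),
    ("control", Valence.POSITIVE): (0.89, 0.12, 2.40),
    ("melancholic", Valence.NEGATIVE): (0.93, 0.08, 2.88),
    ("non_melancholic", Valence.NEGATIVE): (0.96, 0.06, 3.31),
    ("control", Valence.NEGATIVE): (0.93, 0.07, 2.95),
    ("melancholic", Valence.NEUTRAL): (0.75, 0.20, 1.52),
    ("non_melancholic", Valence.NEUTRAL): (0.80, 0.20, 1.68),
    ("control", Valence.NEUTRAL): (0.84, 0.16, 1.99),
}
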