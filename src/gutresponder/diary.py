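"""Defecation diaries and their conversion to condition-labelled intervals.

A crossover trial records, for every subject and day, how many bowel
movements occurred and which study period the day belongs to.  The interval
model consumes *intervals between successive movements*, so daily counts are
expanded to event times: a day with ``f`` events places them at fractions
``j/f`` of the day (``j = 1..f``), i.e. the interval between events on a day
with frequency ``f`` is ``24 h / f``.  A subject reporting exactly one
movement per day therefore yields intervals of exactly 24 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

CONDITIONS = ("baseline", "placebo", "test")


class DiaryValidationError(ValueError):
    """A diary or design violates a structural invariant."""


class EmptySeriesError(DiaryValidationError):
    """Fewer than two events: no interval can be formed."""


@dataclass(frozen=True)
class DiaryDay:
    """One diary row: a day's bowel-movement count and its condition label."""

    day_index: int
    count: int
    condition: str

    def __post_init__(self) -> None:
        if self.count < 0 or int(self.count) != self.count:
            raise DiaryValidationError(
                f"day {self.day_index}: count must be a non-negative integer, "
                f"got {self.count!r}"
            )
        if self.condition not in CONDITIONS:
            raise DiaryValidationError(
                f"day {self.day_index}: condition {self.condition!r} not in "
                f"{CONDITIONS}"
            )


@dataclass(frozen=True)
class DefecationDiary:
    """Ordered daily bowel-movement counts for one subject.

    ``days`` must have strictly increasing, gap-free ``day_index`` values;
    every day carries exactly one condition label from
    ``{"baseline", "placebo", "test"}``.
    """

    subject_id: str
    days: tuple[DiaryDay, ...]

    def __post_init__(self) -> None:
        if not self.days:
            raise DiaryValidationError(f"{self.subject_id}: diary is empty")
        object.__setattr__(self, "days", tuple(self.days))
        idx = [d.day_index for d in self.days]
        for prev, cur, row in zip(idx, idx[1:], range(1, len(idx))):
            if cur != prev + 1:
                raise DiaryValidationError(
                    f"{self.subject_id}: day_index gap between rows "
                    f"{row - 1} and {row} ({prev} -> {cur})"
                )

    @property
    def counts(self) -> list[int]:
        return [d.count for d in self.days]

    @property
    def conditions(self) -> list[str]:
        return [d.condition for d in self.days]

    @property
    def total_events(self) -> int:
        return sum(d.count for d in self.days)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "day_index": [d.day_index for d in self.days],
                "count": [d.count for d in self.days],
                "condition": [d.condition for d in self.days],
            }
        )


@dataclass(frozen=True)
class IntervalSeries:
    """Ordered bowel-movement intervals for one subject.

    ``lengths`` are strictly positive times in days; ``conditions`` holds the
    label of the day on which each interval *ends*.  ``exact_lengths`` keeps
    the rational day-fraction representation so that the zero-variance check
    is exact.
    """

    subject_id: str
    lengths: tuple[float, ...]
    conditions: tuple[str, ...]
    exact_lengths: tuple[Fraction, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.conditions):
            raise DiaryValidationError(
                f"{self.subject_id}: {len(self.lengths)} lengths vs "
                f"{len(self.conditions)} condition labels"
            )
        if any(t <= 0 for t in self.lengths):
            raise DiaryValidationError(
                f"{self.subject_id}: interval lengths must be > 0"
            )
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise DiaryValidationError(
                f"{self.subject_id}: unknown condition labels {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass(frozen=True)
class StudyDesign:
    """Two-arm crossover layout: which days belong to which period.

    Periods are half-open day-index ranges ``[start, end)`` and must be
    contiguous: pre-observation, intervention 1, washout, intervention 2.
    ``arm`` decides which intervention period carries the test supplement
    (arm A: intervention 1; arm B: intervention 2); the other intervention
    period is the placebo.  ``timepoints`` maps the six sampling labels
    C1-C3 / T1-T3 to day indices.
    """

    arm: str
    pre: tuple[int, int]
    intervention1: tuple[int, int]
    washout: tuple[int, int]
    intervention2: tuple[int, int]
    timepoints: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ("A", "B"):
            raise DiaryValidationError(f"arm must be 'A' or 'B', got {self.arm!r}")
        spans = [self.pre, self.intervention1, self.washout, self.intervention2]
        for (a, b) in spans:
            if b <= a:
                raise DiaryValidationError(f"empty or inverted period ({a}, {b})")
        for (_, b), (a2, _) in zip(spans, spans[1:]):
            if b != a2:
                raise DiaryValidationError(
                    f"periods must be contiguous; gap/overlap at day {b} vs {a2}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (self.pre[0], self.intervention2[1])

    @property
    def test_period(self) -> tuple[int, int]:
        return self.intervention1 if self.arm == "A" else self.intervention2

    @property
    def placebo_period(self) -> tuple[int, int]:
        return self.intervention2 if self.arm == "A" else self.intervention1

    def condition_of_day(self, day_index: int) -> str:
        lo, hi = self.span
        if not lo <= day_index < hi:
            raise DiaryValidationError(
                f"day {day_index} outside design span [{lo}, {hi})"
            )
        t0, t1 = self.test_period
        if t0 <= day_index < t1:
            return "test"
        p0, p1 = self.placebo_period
        if p0 <= day_index < p1:
            return "placebo"
        return "baseline"


def label_conditions(day_indices: Iterable[int], design: StudyDesign) -> list[str]:
    """Condition label for each day: test / placebo intervention period or
    baseline (pre-observation and washout)."""
    return [design.condition_of_day(d) for d in day_indices]


def intervals_from_daily_counts(diary: DefecationDiary) -> IntervalSeries:
    """Expand daily counts into successive-event intervals.

    Events on a day with count ``f`` sit at ``(j/f) * 24 h`` from the start of
    the day; intervals are the differences of consecutive event times, the
    leading span before the first event is discarded, and each interval is
    labelled with the condition of the day on which it ends.  Zero-count days
    contribute their full 24 h to the interval ending at the next event.
    """
    events: list[tuple[Fraction, str]] = []  # (event time in days, end-day condition)
    for pos, day in enumerate(diary.days):
        f = day.count
        for j in range(1, f + 1):
            events.append((pos + Fraction(j, f), day.condition))
    if len(events) < 2:
        raise EmptySeriesError(
            f"{diary.subject_id}: need at least two events to form an interval, "
            f"got {len(events)}"
        )
    exact = tuple(b[0] - a[0] for a, b in zip(events, events[1:]))
    conditions = tuple(b[1] for b in events[1:])
    return IntervalSeries(
        subject_id=diary.subject_id,
        lengths=tuple(float(x) for x in exact),
        conditions=conditions,
        exact_lengths=exact,
    )


def zero_variance_flag(series: IntervalSeries) -> bool:
    """True iff every interval has the same length.

    A subject whose intervals are all identical (e.g. exactly one movement a
    day for the whole trial, 24 h throughout) carries no information about
    condition effects and must be excluded before model fitting.
    """
    if len(series) == 0:
        raise EmptySeriesError(f"{series.subject_id}: empty interval series")
    vals: Sequence = (
        series.exact_lengths if series.exact_lengths is not None else series.lengths
    )
    return all(v == vals[0] for v in vals)


def prepare_interval_series(
    diaries: Iterable[DefecationDiary],
) -> tuple[list[IntervalSeries], list[str]]:
    """Expand diaries to interval series, excluding unusable subjects.

    A subject is excluded (and reported by id) when the diary holds fewer
    than two events or when all derived intervals are identical — both make
    the interval model degenerate for that subject.
    """
    series: list[IntervalSeries] = []
    excluded: list[str] = []
    for d in diaries:
        try:
            s = intervals_from_daily_counts(d)
        except EmptySeriesError:
            excluded.append(d.subject_id)
            continue
        if zero_variance_flag(s):
            excluded.append(d.subject_id)
        else:
            series.append(s)
    return series, excluded


# ---------------------------------------------------------------------------
# Table I/O (single TSV dialect: header row, UTF-8, '.' decimal)


def diaries_to_tsv(diaries: Iterable[DefecationDiary], path) -> None:
    pd.concat([d.to_frame() for d in diaries], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def diaries_from_tsv(path) -> list[DefecationDiary]:
    """Read diaries from a TSV with columns subject_id, day_index, count,
    condition (a ``period_label`` column is accepted as a synonym)."""
    df = pd.read_csv(path, sep="\t")
    if "condition" not in df.columns and "period_label" in df.columns:
        df = df.rename(columns={"period_label": "condition"})
    required = {"subject_id", "day_index", "count", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise DiaryValidationError(f"diary table missing columns {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("day_index")
        days = tuple(
            DiaryDay(int(r.day_index), int(r.count), str(r.condition))
            for r in grp.itertuples()
        )
        out.append(DefecationDiary(subject_id=str(sid), days=days))
    return out
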