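"""Diel phase segmentation of the 24-h illumination cycle.

The analysis splits each day into four quarters — two illuminated day
phases (D1 08:00–15:30, D2 15:30–00:00) and two dark night phases
(N1 01:00–04:00, N2 04:00–07:00) — and excludes the two transition hours
around the dimming ramps (T1 00:00–01:00 sundown, T2 07:00–08:00 sunrise)
where the light intensity is changing.  Intervals are half-open
[start, end); an end of 00:00 means 24:00 of the same day, so D2 belongs
wholly to its start date and every phase occurrence lies within one
calendar day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "PhaseSchedule",
    "DEFAULT_SCHEDULE",
    "ANALYSIS_PHASES",
    "TRANSITIONS",
    "label_timestamp",
    "phase_day",
    "phase_minutes_per_day",
    "summarize",
]

ANALYSIS_PHASES: tuple[str, ...] = ("D1", "D2", "N1", "N2")
TRANSITIONS: tuple[str, ...] = ("T1", "T2")


def _to_minutes(t: time) -> int:
    return t.hour * 60 + t.minute


@dataclass(frozen=True)
class PhaseSchedule:
    """Half-open clock-time intervals partitioning the 24-h day.

    ``intervals`` maps a phase label to (start, end) clock times; an end of
    ``00:00`` is read as 24:00.  The labels must tile the day exactly.
    """

    intervals: dict[str, tuple[time, time]] = field(
        default_factory=lambda: {
            "T1": (time(0, 0), time(1, 0)),
            "N1": (time(1, 0), time(4, 0)),
            "N2": (time(4, 0), time(7, 0)),
            "T2": (time(7, 0), time(8, 0)),
            "D1": (time(8, 0), time(15, 30)),
            "D2": (time(15, 30), time(0, 0)),
        }
    )

    def __post_init__(self) -> None:
        spans = sorted(self.interval_minutes(p) for p in self.intervals)
        if spans[0][0] != 0 or spans[-1][1] != 1440:
            raise ConfigurationError("phase schedule must cover 00:00-24:00")
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if e0 != s1:
                raise ConfigurationError(
                    f"phase schedule has a gap or overlap at minute {e0}"
                )

    def interval_minutes(self, phase: str) -> tuple[int, int]:
        """(start, end) of a phase in minutes after midnight; end may be 1440."""
        try:
            start, end = self.intervals[phase]
        except KeyError:
            raise ConfigurationError(f"unknown phase {phase!r}") from None
        s, e = _to_minutes(start), _to_minutes(end)
        if e <= s:
            if e == 0:
                e = 1440
            else:
                raise ConfigurationError(f"phase {phase!r} must not wrap past midnight")
        return s, e

    def lookup_table(self) -> np.ndarray:
        """Minute-of-day → label array of length 1440."""
        table = np.empty(1440, dtype=object)
        for phase in self.intervals:
            s, e = self.interval_minutes(phase)
            table[s:e] = phase
        return table


DEFAULT_SCHEDULE = PhaseSchedule()


def label_timestamp(ts: datetime, schedule: PhaseSchedule = DEFAULT_SCHEDULE) -> str:
    """Phase label of a timestamp; transitions return their own label (T1/T2)."""
    minute = ts.hour * 60 + ts.minute
    return schedule.lookup_table()[minute]


def is_excluded(label: str) -> bool:
    """True for the sundown/sunrise transition labels excluded from analysis."""
    return label in TRANSITIONS


def phase_day(ts: datetime, schedule: PhaseSchedule = DEFAULT_SCHEDULE) -> date:
    """Calendar date owning the phase occurrence containing ``ts``.

    With the default schedule every phase starts and ends within one
    calendar day, so this is simply the timestamp's date.  Transition
    timestamps have no analysis phase and raise.
    """
    label = label_timestamp(ts, schedule)
    if is_excluded(label):
        raise ConfigurationError(f"timestamp {ts} falls in excluded transition {label}")
    return ts.date()


def phase_minutes_per_day(schedule: PhaseSchedule = DEFAULT_SCHEDULE) -> dict[str, int]:
    """Minutes per day covered by each label (450/510/180/180/60/60 default)."""
    return {
        p: schedule.interval_minutes(p)[1] - schedule.interval_minutes(p)[0]
        for p in schedule.intervals
    }


def assign_phases(index: pd.DatetimeIndex, schedule: PhaseSchedule = DEFAULT_SCHEDULE) -> np.ndarray:
    """Vectorized phase label per timestamp."""
    minute = index.hour * 60 + index.minute
    return schedule.lookup_table()[np.asarray(minute)]


def summarize(dataset, schedule: PhaseSchedule = DEFAULT_SCHEDULE) -> pd.DataFrame:
    """Per-day, per-phase, per-channel mean/SD/count table.

    Transition samples are excluded.  SD is the sample standard deviation
    (n−1 denominator), reported as 0 when n = 1.  Days or phases with zero
    samples are simply absent.

    Returns a tidy DataFrame with columns
    ``day, phase, channel, mean, sd, n``.
    """
    frame = dataset.frame
    if frame.empty:
        raise ConfigurationError("cannot summarize an empty dataset")
    labels = assign_phases(frame.index, schedule)
    keep = ~np.isin(labels, TRANSITIONS)
    sub = frame.loc[keep]
    long = sub.reset_index(names="timestamp").melt(
        id_vars="timestamp", var_name="channel", value_name="temp"
    )
    long = long.dropna(subset=["temp"])
    long["day"] = long["timestamp"].dt.date
    lookup = schedule.lookup_table()
    minute = long["timestamp"].dt.hour * 60 + long["timestamp"].dt.minute
    long["phase"] = lookup[minute.to_numpy()]
    grouped = long.groupby(["day", "phase", "channel"], sort=True, observed=True)["temp"]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out
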