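"""Reading, writing, merging and validating multi-channel temperature logs.

The native dialect mirrors the serial-logger output of the instrumented
columns: semicolon-separated text, one header row naming the channels
("Timestamp;Living Top;Living Bottom;Control Top;Control Bottom;Incubator"),
ISO-8601 naive local timestamps, one row per sampling tick.  Weekly files
are merged, deduplicated and gap-checked here; interruptions are never
interpolated — a day simply contributes fewer samples and may fail the
valid-day coverage rule.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ChannelError, ConfigurationError

__all__ = [
    "CHANNELS",
    "CHANNEL_ALIASES",
    "LogDataset",
    "read_log",
    "write_log",
    "merge_logs",
    "valid_days",
]

#: Canonical channel identifiers.  Internal probes sit inside the sediment;
#: the ``*_ext`` references are taped to the outside wall at matching
#: heights; ``incubator`` is the chamber's ambient reference.
CHANNELS: tuple[str, ...] = (
    "living_top",
    "living_bottom",
    "control_top",
    "control_bottom",
    "incubator",
    "living_top_ext",
    "living_bottom_ext",
    "control_top_ext",
    "control_bottom_ext",
)

_TIME_ALIASES = {"timestamp", "time", "datetime", "date time", "date"}


def _norm(name: str) -> str:
    return re.sub(r"[\s_\-]+", " ", name.strip().lower())


#: Header-name → canonical channel mapping (normalized: lowercase, separators
#: collapsed to single spaces).
CHANNEL_ALIASES: dict[str, str] = {}
for _ch in CHANNELS:
    CHANNEL_ALIASES[_norm(_ch)] = _ch
    CHANNEL_ALIASES[_norm(_ch.replace("_ext", " external"))] = _ch
for _alias, _ch in {
    "t lt": "living_top",
    "t lb": "living_bottom",
    "t ct": "control_top",
    "t cb": "control_bottom",
    "t inc": "incubator",
    "inc": "incubator",
    "t lt ext": "living_top_ext",
    "t lb ext": "living_bottom_ext",
    "t ct ext": "control_top_ext",
    "t cb ext": "control_bottom_ext",
}.items():
    CHANNEL_ALIASES[_alias] = _ch


@dataclass
class LogDataset:
    """An ordered multi-channel temperature log.

    ``frame`` has a strictly increasing naive ``DatetimeIndex`` and one float
    column per declared channel (NaN where a reading is missing).
    ``sampling_period`` is the nominal tick in seconds; an index spacing
    larger than 3× the nominal period counts as a logging gap.
    """

    frame: pd.DataFrame
    sampling_period: float = 60.0
    n_dropped_values: int = 0
    n_skipped_rows: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.frame.index, pd.DatetimeIndex):
            raise ConfigurationError("LogDataset frame must be indexed by datetime")
        if not self.frame.index.is_monotonic_increasing or self.frame.index.has_duplicates:
            raise ConfigurationError("timestamps must be strictly increasing")
        if self.sampling_period <= 0:
            raise ConfigurationError("sampling_period must be positive")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def gap_report(self) -> list[tuple[datetime, datetime]]:
        """Intervals where consecutive timestamps are > 3× the nominal period."""
        idx = self.frame.index
        if len(idx) < 2:
            return []
        spacing = np.diff(idx.view("int64")) / 1e9
        holes = np.nonzero(spacing > 3.0 * self.sampling_period)[0]
        return [(idx[i].to_pydatetime(), idx[i + 1].to_pydatetime()) for i in holes]

    def __len__(self) -> int:
        return len(self.frame)


def _map_headers(names: Sequence[str]) -> tuple[str, list[str]]:
    """Resolve a raw header row into (time column, canonical channel names)."""
    time_col = None
    mapped: list[str] = []
    for raw in names:
        key = _norm(raw)
        if key in _TIME_ALIASES and time_col is None:
            time_col = raw
        elif key in CHANNEL_ALIASES:
            mapped.append(CHANNEL_ALIASES[key])
        else:
            known = sorted(set(CHANNEL_ALIASES) | _TIME_ALIASES)
            raise ChannelError(
                f"unrecognized log header {raw!r}; recognized names: {', '.join(known)}"
            )
    if time_col is None:
        raise ChannelError("log file has no timestamp column")
    return time_col, mapped


def read_log(
    source: str | Path | io.TextIOBase,
    *,
    delimiter: str = ";",
    sampling_period: float = 60.0,
    plausible: tuple[float, float] = (-10.0, 60.0),
) -> LogDataset:
    """Parse a native-dialect temperature log into a :class:`LogDataset`.

    Rows with unparseable timestamps are skipped and tallied in
    ``n_skipped_rows``; individual readings outside the plausibility window
    are dropped (set to NaN) and tallied in ``n_dropped_values``.  Duplicate
    timestamps keep the first occurrence.
    """
    raw = pd.read_csv(source, sep=delimiter, dtype=str, skipinitialspace=True)
    time_col, channels = _map_headers(list(raw.columns))
    ts = pd.to_datetime(raw[time_col], errors="coerce", format="ISO8601")
    skipped = int(ts.isna().sum())
    keep = ~ts.isna()

    data = raw.loc[keep, [c for c in raw.columns if c != time_col]].copy()
    data.columns = channels
    data = data.apply(pd.to_numeric, errors="coerce")
    lo, hi = plausible
    out_of_range = ((data < lo) | (data > hi)).to_numpy().sum()
    data = data.where((data >= lo) & (data <= hi))

    data.index = pd.DatetimeIndex(ts[keep])
    data = data[~data.index.duplicated(keep="first")].sort_index()
    return LogDataset(
        frame=data,
        sampling_period=sampling_period,
        n_dropped_values=int(out_of_range),
        n_skipped_rows=skipped,
    )


def write_log(
    dataset: LogDataset,
    target: str | Path | io.TextIOBase,
    *,
    delimiter: str = ";",
    precision: int = 4,
) -> None:
    """Write a dataset in the native dialect (inverse of :func:`read_log`)."""
    frame = dataset.frame.copy()
    pretty = {c: c.replace("_ext", " Ext").replace("_", " ").title() for c in frame.columns}
    frame = frame.rename(columns=pretty)
    frame.index.name = "Timestamp"
    frame.to_csv(
        target,
        sep=delimiter,
        float_format=f"%.{precision}f",
        date_format="%Y-%m-%dT%H:%M:%S",
    )


def merge_logs(datasets: Iterable[LogDataset]) -> LogDataset:
    """Merge sequential log files into one ordered, deduplicated dataset.

    All inputs must declare the same channel set.  Exact-duplicate
    timestamps keep the first occurrence (in input order), so the merge is
    idempotent and order-insensitive on consistent data.
    """
    datasets = list(datasets)
    if not datasets:
        raise ConfigurationError("no datasets to merge")
    ref = set(datasets[0].channels)
    for ds in datasets[1:]:
        if set(ds.channels) != ref:
            diff = ref.symmetric_difference(ds.channels)
            raise ChannelError(f"channel sets differ between files: {sorted(diff)}")
    frame = pd.concat([ds.frame for ds in datasets]).sort_index(kind="stable")
    frame = frame[~frame.index.duplicated(keep="first")]
    return LogDataset(
        frame=frame,
        sampling_period=datasets[0].sampling_period,
        n_dropped_values=sum(ds.n_dropped_values for ds in datasets),
        n_skipped_rows=sum(ds.n_skipped_rows for ds in datasets),
    )


def valid_days(
    dataset: LogDataset,
    phase: str,
    schedule=None,
    min_coverage: float = 0.9,
    channel: str | None = None,
) -> tuple[int, list[date]]:
    """Count calendar days with sufficient sample coverage in one diel phase.

    A day is valid for a phase when the fraction of expected samples
    (phase duration / nominal sampling period) actually present is at least
    ``min_coverage``.  With ``channel`` set, only rows where that channel has
    a reading count as present; otherwise row presence suffices.  Mirrors
    the "valid measurement days without technical interruptions" rule used
    for monthly aggregates.
    """
    from .phases import DEFAULT_SCHEDULE, phase_minutes_per_day

    if schedule is None:
        schedule = DEFAULT_SCHEDULE
    if not 0.0 < min_coverage <= 1.0:
        raise ConfigurationError("min_coverage must lie in (0, 1]")
    if len(dataset) == 0:
        return 0, []

    start, end = schedule.interval_minutes(phase)
    expected = phase_minutes_per_day(schedule)[phase] * 60.0 / dataset.sampling_period
    idx = dataset.frame.index
    minute = idx.hour * 60 + idx.minute + idx.second / 60.0
    in_phase = (minute >= start) & (minute < end)
    if channel is not None:
        if channel not in dataset.frame.columns:
            raise ChannelError(f"channel {channel!r} not in dataset")
        in_phase &= dataset.frame[channel].notna().to_numpy()

    counts = pd.Series(1, index=idx[in_phase]).groupby(idx[in_phase].date).size()
    good = sorted(d for d, n in counts.items() if n / expected >= min_coverage)
    return len(good), good
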