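"""Difference series and their phase/monthly aggregates.

Two families of differences drive the analysis:

* vertical gradients within one column, ``dT_TB = T_top − T_bottom``,
  computed from the internal probes (``*_int``) and from the external wall
  references (``*_ext``) — a living-column internal gradient exceeding both
  its own external gradient and the control's points to localized heat
  production in the oxygen-rich upper sediment;
* living-minus-control differences at matching heights, ``dT_top`` and
  ``dT_bott``, which track a persistent metabolic temperature offset.

Aggregation is hierarchical throughout: raw samples → per-day phase means →
phase boxplot statistics or month-level means over valid days.  Pooling raw
samples across days would weight interrupted days unequally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ChannelError, ConfigurationError
from .logio import LogDataset
from .phases import ANALYSIS_PHASES, DEFAULT_SCHEDULE, PhaseSchedule, TRANSITIONS, assign_phases

__all__ = [
    "KIND_PAIRS",
    "DifferenceSeries",
    "difference_series",
    "per_day_phase_means",
    "phase_boxplot_stats",
    "monthly_aggregate",
]

#: Difference kind → (minuend channel, subtrahend channel).
KIND_PAIRS: dict[str, tuple[str, str]] = {
    "dT_TB_int_living": ("living_top", "living_bottom"),
    "dT_TB_int_control": ("control_top", "control_bottom"),
    "dT_TB_ext_living": ("living_top_ext", "living_bottom_ext"),
    "dT_TB_ext_control": ("control_top_ext", "control_bottom_ext"),
    "dT_top": ("living_top", "control_top"),
    "dT_bott": ("living_bottom", "control_bottom"),
}


@dataclass
class DifferenceSeries:
    """Pointwise channel difference at shared timestamps."""

    kind: str
    minuend: str
    subtrahend: str
    samples: pd.Series  # DatetimeIndex → °C difference
    sampling_period: float = 60.0
    n_unmatched: int = 0


def difference_series(
    dataset: LogDataset, kind: str, *, snap: bool = True
) -> DifferenceSeries:
    """Compute one named difference series from a dataset.

    Timestamps are snapped to the nominal sampling grid (round to nearest
    ``sampling_period``) before pairing, guarding against logger jitter;
    samples where either channel is missing are dropped and tallied.
    """
    try:
        minuend, subtrahend = KIND_PAIRS[kind]
    except KeyError:
        raise ConfigurationError(
            f"unknown difference kind {kind!r}; known: {sorted(KIND_PAIRS)}"
        ) from None
    for ch in (minuend, subtrahend):
        if ch not in dataset.frame.columns:
            raise ChannelError(f"dataset lacks channel {ch!r} required for {kind}")

    frame = dataset.frame[[minuend, subtrahend]]
    if snap:
        period = pd.Timedelta(seconds=dataset.sampling_period)
        snapped = frame.index.round(period)
        frame = frame.set_axis(snapped)
        frame = frame[~frame.index.duplicated(keep="first")]
    diff = frame[minuend] - frame[subtrahend]
    n_unmatched = int(diff.isna().sum())
    diff = diff.dropna()
    return DifferenceSeries(
        kind=kind,
        minuend=minuend,
        subtrahend=subtrahend,
        samples=diff,
        sampling_period=dataset.sampling_period,
        n_unmatched=n_unmatched,
    )


def per_day_phase_means(
    series: DifferenceSeries,
    schedule: PhaseSchedule = DEFAULT_SCHEDULE,
    min_coverage: float | None = None,
) -> pd.DataFrame:
    """Per-day, per-phase mean/SD/count of a difference series.

    Columns: ``day, phase, mean, sd, n``; transitions excluded.  With
    ``min_coverage`` set, days whose sample count falls below that fraction
    of the phase's expected count (duration / sampling period) are dropped —
    the valid-day rule used for aggregates.
    """
    s = series.samples
    if s.empty:
        return pd.DataFrame(columns=["day", "phase", "mean", "sd", "n"])
    labels = assign_phases(s.index, schedule)
    keep = ~np.isin(labels, TRANSITIONS)
    df = pd.DataFrame(
        {"day": s.index.date[keep], "phase": labels[keep], "value": s.to_numpy()[keep]}
    )
    out = (
        df.groupby(["day", "phase"], sort=True, observed=True)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    if min_coverage is not None:
        from .phases import phase_minutes_per_day

        minutes = phase_minutes_per_day(schedule)
        expected = out["phase"].map(
            {p: m * 60.0 / series.sampling_period for p, m in minutes.items()}
        )
        out = out[out["n"] / expected >= min_coverage].reset_index(drop=True)
    return out


def phase_boxplot_stats(
    series: DifferenceSeries,
    schedule: PhaseSchedule = DEFAULT_SCHEDULE,
    phase: str = "D2",
) -> dict[str, float] | None:
    """Five-number summary + mean/SD of the per-day phase means of a series.

    The distribution summarized is the set of daily phase means (one value
    per day), matching phase-wise boxplot presentation.  Quartiles use
    linear interpolation between order statistics.  Returns ``None`` when
    the phase has no covered days.
    """
    daily = per_day_phase_means(series, schedule)
    vals = daily.loc[daily["phase"] == phase, "mean"].to_numpy(dtype=float)
    if vals.size == 0:
        import warnings

        warnings.warn(f"no covered days for phase {phase!r} in {series.kind}")
        return None
    q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
    return {
        "min": float(vals.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "n_days": int(vals.size),
    }


def monthly_aggregate(
    per_day: pd.DataFrame,
    phase: str,
    group_col: str | None = None,
    value_col: str = "mean",
) -> pd.DataFrame:
    """Month-level means over per-day phase means.

    ``per_day`` is a tidy per-day table (from :func:`per_day_phase_means` or
    the channel summary) with columns ``day, phase, <value_col>`` and
    optionally a ``group_col`` (channel or difference kind).  The month mean
    is the mean of the daily phase means over the month's valid days, the SD
    is taken over the same daily means, and ``valid_days`` reports how many
    days contributed.  Months without coverage are absent.
    """
    df = per_day[per_day["phase"] == phase].copy()
    if df.empty:
        cols = ["month", "phase"] + ([group_col] if group_col else []) + ["mean", "sd", "valid_days"]
        return pd.DataFrame(columns=cols)
    df["month"] = pd.PeriodIndex(pd.DatetimeIndex(df["day"]), freq="M")
    keys = ["month"] + ([group_col] if group_col else [])
    out = (
        df.groupby(keys, sort=True, observed=True)[value_col]
        .agg(mean="mean", sd="std", valid_days="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    out.insert(1, "phase", phase)
    return out
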