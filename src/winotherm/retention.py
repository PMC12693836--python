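"""Insulation-experiment statistics: temperature retention metrics.

Wrapping both columns in insulation (aluminum foil, optionally with a
polyethylene layer) suppresses lateral heat exchange with the incubator.
If the living column carries an internal heat source, its living-minus-
control temperature difference should rise during the wrap.  Two phase-
resolved statistics quantify this:

* **ΔΔT (temperature retention)** — the highest per-day phase mean of the
  difference series during the insulation window, minus the mean over the
  preceding ``baseline_days`` valid phase-days;
* **ΔΔT_Steady (steady-state retention)** — the mean over the first
  ``post_days`` valid phase-days after removal, minus the same baseline,
  capturing whether the elevation persists once the wrap is off.

Both are offset-invariant in the underlying difference series and are
judged against the sensor quantization step (0.0625 °C at 12 bits): values
below it are within single-sensor precision and not interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Literal

import numpy as np
import pandas as pd

from .apparatus import SensorSpec
from .diffstats import DifferenceSeries, per_day_phase_means
from .errors import InsufficientCoverageError
from .phases import ANALYSIS_PHASES, DEFAULT_SCHEDULE, PhaseSchedule, assign_phases

__all__ = [
    "InsulationEvent",
    "RetentionResult",
    "retention_stats",
    "precision_flag",
]


@dataclass(frozen=True)
class InsulationEvent:
    """One insulation window applied to both columns."""

    start: datetime
    end: datetime
    wrap: str = "foil"  # e.g. "foil", "foil+PE"
    notes: str = ""
    #: Factor multiplying the columns' external conductances while wrapped
    #: (used by the simulator; 1.0 = no insulation effect).
    conduct_scale: float = 0.3

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("insulation event must have start < end")
        if not 0.0 < self.conduct_scale <= 1.0:
            raise ValueError("conduct_scale must lie in (0, 1]")


@dataclass(frozen=True)
class RetentionResult:
    """Retention statistics for one region/phase around one event."""

    region: str  # "top" | "bottom" or the difference kind analysed
    phase: str
    delta_delta: float  # ΔΔT, °C
    delta_delta_steady: float  # ΔΔT_Steady, °C
    baseline_mean: float
    during_max_day_mean: float
    post_mean: float
    baseline_days: int
    post_days: int


def _phase_window(day: date, phase: str, schedule: PhaseSchedule) -> tuple[datetime, datetime]:
    s, e = schedule.interval_minutes(phase)
    base = datetime.combine(day, datetime.min.time())
    return base + timedelta(minutes=s), base + timedelta(minutes=e)


def retention_stats(
    delta_series: DifferenceSeries,
    event: InsulationEvent,
    schedule: PhaseSchedule = DEFAULT_SCHEDULE,
    *,
    baseline_days: int = 3,
    post_days: int = 3,
    min_coverage: float = 0.9,
    region: str | None = None,
) -> dict[str, RetentionResult]:
    """Compute ΔΔT and ΔΔT_Steady for every analysis phase around an event.

    Day classification per phase: a day is *during* when its phase window
    overlaps ``[event.start, event.end]`` (partially overlapped days
    contribute only the overlapped portion's mean); baseline days are the
    last ``baseline_days`` valid days whose phase window lies entirely
    before the event, post days the first ``post_days`` valid days entirely
    after it.  Valid means sample coverage ≥ ``min_coverage`` of the
    expected count; interrupted days are skipped, not shrunk into.
    """
    region = region or delta_series.kind
    daily = per_day_phase_means(delta_series, schedule, min_coverage=min_coverage)
    samples = delta_series.samples
    labels = assign_phases(samples.index, schedule)
    results: dict[str, RetentionResult] = {}

    for phase in ANALYSIS_PHASES:
        rows = daily[daily["phase"] == phase]
        day_means = {d: m for d, m in zip(rows["day"], rows["mean"])}
        all_days = sorted(
            set(samples.index.date[labels == phase])
        )
        pre, during, post = [], [], []
        for day in all_days:
            w0, w1 = _phase_window(day, phase, schedule)
            if w1 <= event.start:
                if day in day_means:
                    pre.append(day)
            elif w0 >= event.end:
                if day in day_means:
                    post.append(day)
            else:
                during.append(day)

        if len(pre) < baseline_days:
            raise InsufficientCoverageError(
                f"{region}/{phase}: only {len(pre)} valid baseline day(s) before "
                f"{event.start:%Y-%m-%d}, need {baseline_days}"
            )
        if len(post) < post_days:
            raise InsufficientCoverageError(
                f"{region}/{phase}: only {len(post)} valid post day(s) after "
                f"{event.end:%Y-%m-%d}, need {post_days}"
            )

        # During-days: mean over the portion of the phase window overlapping
        # the event (full window for fully covered days).
        during_means = []
        for day in during:
            w0, w1 = _phase_window(day, phase, schedule)
            lo, hi = max(w0, event.start), min(w1, event.end)
            seg = samples[(samples.index >= lo) & (samples.index < hi)]
            if seg.empty:
                continue
            expected = (hi - lo).total_seconds() / delta_series.sampling_period
            if expected > 0 and len(seg) / expected >= min_coverage:
                during_means.append(float(seg.mean()))
        if not during_means:
            raise InsufficientCoverageError(
                f"{region}/{phase}: no covered day overlaps the insulation window"
            )

        baseline = float(np.mean([day_means[d] for d in pre[-baseline_days:]]))
        post_mean = float(np.mean([day_means[d] for d in post[:post_days]]))
        during_max = max(during_means)
        results[phase] = RetentionResult(
            region=region,
            phase=phase,
            delta_delta=during_max - baseline,
            delta_delta_steady=post_mean - baseline,
            baseline_mean=baseline,
            during_max_day_mean=during_max,
            post_mean=post_mean,
            baseline_days=baseline_days,
            post_days=post_days,
        )
    return results


Flag = Literal["above", "below", "at-threshold"]


def precision_flag(value: float, sensor: SensorSpec, atol: float = 1e-12) -> Flag:
    """Classify a retention statistic against the sensor quantization step.

    Values whose magnitude does not exceed one quantization step cannot be
    distinguished from digitization artifacts of a single sensor pair.
    """
    mag = abs(value)
    if abs(mag - sensor.resolution) <= atol:
        return "at-threshold"
    return "above" if mag > sensor.resolution else "below"


def flag_result(result: RetentionResult, sensor: SensorSpec) -> dict[str, Flag]:
    """Precision flags for both statistics of a retention result."""
    return {
        "delta_delta": precision_flag(result.delta_delta, sensor),
        "delta_delta_steady": precision_flag(result.delta_delta_steady, sensor),
    }
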