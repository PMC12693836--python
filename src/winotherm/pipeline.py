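"""End-to-end orchestration: ingest or simulate, analyse, report.

A run takes exactly one input source — a set of native-dialect log files or
a simulation scenario — and produces a bundle of tidy semicolon-delimited
tables, best-effort figures (time series, phase boxplots, monthly panels,
retention bars with the sensor-precision line) and a JSON manifest (config
hash, package version, seed) that fully determines the numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .apparatus import DS18B20
from .diffstats import (
    KIND_PAIRS,
    difference_series,
    monthly_aggregate,
    per_day_phase_means,
    phase_boxplot_stats,
)
from .disttest import bin_differences, mwu_binned, mwu_raw
from .errors import ConfigurationError
from .logio import LogDataset, merge_logs, read_log
from .phases import ANALYSIS_PHASES, DEFAULT_SCHEDULE, PhaseSchedule, summarize
from .retention import InsulationEvent, flag_result, retention_stats
from .simulate import ColumnSimConfig, simulate

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (log files XOR a scenario)."""

    outdir: Path
    log_paths: tuple[str, ...] = ()
    scenario: ColumnSimConfig | None = None
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    events: tuple[InsulationEvent, ...] = ()
    min_coverage: float = 0.9
    do_gradients: bool = True
    do_longterm: bool = True
    do_retention: bool = True
    do_disttest: bool = True
    make_figures: bool = True
    seed: int | None = None  # overrides the scenario seed when set

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if bool(self.log_paths) == (self.scenario is not None):
            raise ConfigurationError("exactly one input source: log files or a scenario")


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {"__type__": type(o).__name__, **dataclasses.asdict(o)}
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep=";", index=False, float_format="%.6f")
    return path


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute ingest → phases → differences → retention/disttest → report.

    Returns a mapping of bundle item names to written paths.  Numeric tables
    are the authoritative outputs; figures are illustrative.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}

    # --- ingest ---
    if config.log_paths:
        datasets = [read_log(p) for p in config.log_paths]
        if not datasets:
            raise ConfigurationError("no input datasets")
        dataset = merge_logs(datasets)
        events = config.events
    else:
        scenario = config.scenario
        assert scenario is not None
        if config.seed is not None:
            scenario = dataclasses.replace(scenario, seed=config.seed)
        result = simulate(scenario)
        dataset = result.dataset
        events = config.events or scenario.insulation

    schedule = config.schedule

    # --- per-phase channel summaries ---
    summaries = summarize(dataset, schedule)
    bundle["phase_summaries"] = _write(summaries, out / "phase_summaries.csv")

    # --- difference series for every kind the channels support ---
    series = {}
    for kind, (a, b) in KIND_PAIRS.items():
        if a in dataset.frame.columns and b in dataset.frame.columns:
            series[kind] = difference_series(dataset, kind)

    if config.do_gradients and series:
        daily_rows = []
        box_rows = []
        for kind, s in series.items():
            daily = per_day_phase_means(s, schedule, min_coverage=config.min_coverage)
            daily.insert(0, "kind", kind)
            daily_rows.append(daily)
            for phase in ANALYSIS_PHASES:
                stats = phase_boxplot_stats(s, schedule, phase)
                if stats is not None:
                    box_rows.append({"kind": kind, "phase": phase, **stats})
        bundle["gradients_daily"] = _write(
            pd.concat(daily_rows, ignore_index=True), out / "gradients_daily.csv"
        )
        bundle["gradients_boxstats"] = _write(
            pd.DataFrame(box_rows), out / "gradients_boxstats.csv"
        )

    if config.do_longterm and series:
        monthly_rows = []
        for kind, s in series.items():
            daily = per_day_phase_means(s, schedule, min_coverage=config.min_coverage)
            for phase in ANALYSIS_PHASES:
                m = monthly_aggregate(daily, phase)
                m.insert(0, "kind", kind)
                monthly_rows.append(m)
        bundle["longterm_monthly"] = _write(
            pd.concat(monthly_rows, ignore_index=True), out / "longterm_monthly.csv"
        )

    if config.do_retention and events:
        rows = []
        for kind in ("dT_top", "dT_bott"):
            if kind not in series:
                continue
            region = "top" if kind == "dT_top" else "bottom"
            for ev in events:
                results = retention_stats(
                    series[kind], ev, schedule, min_coverage=config.min_coverage,
                    region=region,
                )
                for phase, r in results.items():
                    flags = flag_result(r, DS18B20)
                    rows.append(
                        {
                            "region": r.region,
                            "phase": phase,
                            "event_start": ev.start,
                            "wrap": ev.wrap,
                            "delta_delta": r.delta_delta,
                            "delta_delta_steady": r.delta_delta_steady,
                            "baseline_mean": r.baseline_mean,
                            "flag_delta_delta": flags["delta_delta"],
                            "flag_steady": flags["delta_delta_steady"],
                        }
                    )
        if rows:
            bundle["retention"] = _write(pd.DataFrame(rows), out / "retention.csv")

    if config.do_disttest and "dT_TB_int_living" in series and "dT_TB_int_control" in series:
        a = series["dT_TB_int_living"].samples.to_numpy()
        b = series["dT_TB_int_control"].samples.to_numpy()
        binned = mwu_binned(bin_differences(a), bin_differences(b))
        raw = mwu_raw(a, b)
        bundle["disttest"] = _write(
            pd.DataFrame(
                [
                    {"test": "binned_frequencies", "U": binned.U, "p_value": binned.p_value,
                     "method": binned.method, "n1": binned.n1, "n2": binned.n2},
                    {"test": "raw_samples", "U": raw.U, "p_value": raw.p_value,
                     "method": raw.method, "n1": raw.n1, "n2": raw.n2},
                ]
            ),
            out / "disttest.csv",
        )

    if config.make_figures:
        bundle.update(_figures(dataset, series, events, schedule, out))

    manifest = {
        "config_hash": _config_hash(config),
        "winotherm_version": __version__,
        "seed": config.seed
        if config.seed is not None
        else (config.scenario.seed if config.scenario else None),
        "n_records": len(dataset),
        "channels": list(dataset.channels),
        "gaps": [[str(a), str(b)] for a, b in dataset.gap_report],
        "outputs": {k: str(v) for k, v in bundle.items()},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = path
    return bundle


def _figures(dataset, series, events, schedule, out: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made: dict[str, Path] = {}

    fig, ax = plt.subplots(figsize=(10, 4))
    for ch in dataset.frame.columns:
        ax.plot(dataset.frame.index, dataset.frame[ch], lw=0.6, label=ch)
    ax.set_ylabel("temperature (°C)")
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    p = out / "timeseries.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made["fig_timeseries"] = p

    if series:
        fig, axes = plt.subplots(1, len(ANALYSIS_PHASES), figsize=(12, 3.5), sharey=True)
        for ax, phase in zip(axes, ANALYSIS_PHASES):
            labels, data = [], []
            for kind, s in series.items():
                daily = per_day_phase_means(s, schedule)
                vals = daily.loc[daily["phase"] == phase, "mean"]
                if len(vals):
                    labels.append(kind)
                    data.append(vals.to_numpy())
            if data:
                ax.boxplot(data, tick_labels=labels)
                ax.tick_params(axis="x", rotation=90, labelsize=6)
            ax.axhline(DS18B20.accuracy, ls="--", c="grey", lw=0.8)
            ax.set_title(phase)
        axes[0].set_ylabel("ΔT (°C)")
        fig.tight_layout()
        p = out / "phase_boxplots.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made["fig_phase_boxplots"] = p

    return made
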