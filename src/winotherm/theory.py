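"""Heat-balance theory for microbial warming of sediment.

An idealized upper bound on the temperature rise a microbial community can
produce in sediment follows from a lumped heat balance: a population of
``N`` cells per kg of sediment, each dissipating a metabolic heat rate
``q`` (W per cell), delivers a volumetric power density ``p = q · N``
(W kg⁻¹) into a matrix of specific heat capacity ``c_s``
(J kg⁻¹ °C⁻¹), heating it (losses neglected) at

    dT/dt = p / c_s            [°C s⁻¹]  =  3600 · p / c_s  [°C h⁻¹]

With literature per-cell heat rates for *E. coli* (0.8 pW aerobic, 0.2 pW
anaerobic) and an environmental abundance of 5.725×10¹² cells per kg of
sediment, the power densities are 4.58 and 1.145 W kg⁻¹, and with a
sediment heat capacity between 2880 and 4180 J kg⁻¹ °C⁻¹ the idealized
heating rates span roughly 3.9–5.7 °C h⁻¹ (aerobic) and 1.0–1.4 °C h⁻¹
(anaerobic).  These are loss-free upper limits; observed effects in real
columns are far smaller.

The module also provides the gravimetric water-content estimator used to
approximate ``c_s`` (oven-drying to constant mass) and a mass-weighted
mixture heat-capacity calculator for sensitivity analysis.  Note the default
``c_s`` range (2880, 4180) is an externally supplied estimate and is *not*
re-derived from the mixture formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .errors import ConfigurationError, NonConvergenceError

__all__ = [
    "SedimentComposition",
    "CellHeatSpec",
    "HeatingRatePrediction",
    "DryingSeries",
    "WaterContentResult",
    "mixture_heat_capacity",
    "heating_rate",
    "power_density",
    "predict_heating_rates",
    "aerobic_anaerobic_gap",
    "water_content_from_drying",
    "prediction_report",
    "DEFAULT_CELL_HEAT",
    "DEFAULT_CS_RANGE",
    "REFERENCE_RATE_BOUNDS",
]

Condition = Literal["aerobic", "anaerobic"]

#: Default sediment heat-capacity range, J kg⁻¹ °C⁻¹ (estimate for a wet
#: freshwater sediment of ~62% water content).
DEFAULT_CS_RANGE: tuple[float, float] = (2880.0, 4180.0)

#: Commonly quoted heating-rate ranges (°C h⁻¹) for the reference scenario,
#: used by :func:`prediction_report` to flag print-precision disagreements.
REFERENCE_RATE_BOUNDS: dict[str, tuple[float, float]] = {
    "aerobic": (3.9, 5.6),
    "anaerobic": (0.9, 1.3),
}

SPECIFIC_HEAT_WATER = 4184.0  # J kg⁻¹ °C⁻¹


@dataclass(frozen=True)
class SedimentComposition:
    """Mass composition and heat-capacity bookkeeping for wet sediment."""

    water_mass_fraction: float = 0.618
    dry_to_fresh_ratio: float = 0.382
    c_dry_range: tuple[float, float] = (910.0, 2400.0)
    c_water: float = SPECIFIC_HEAT_WATER
    c_s_range: tuple[float, float] = DEFAULT_CS_RANGE

    def __post_init__(self) -> None:
        if abs(self.water_mass_fraction + self.dry_to_fresh_ratio - 1.0) > 0.01:
            raise ConfigurationError("water and dry mass fractions must sum to 1 (±0.01)")
        for low, high in (self.c_dry_range, self.c_s_range):
            if not 0 < low <= high:
                raise ConfigurationError("capacity ranges must be positive with low <= high")
        if self.c_water <= 0:
            raise ConfigurationError("c_water must be positive")


@dataclass(frozen=True)
class CellHeatSpec:
    """Per-cell metabolic heat rates and cell abundance per kg sediment."""

    q_aerobic: float = 0.8e-12  # W per cell
    q_anaerobic: float = 0.2e-12  # W per cell
    abundance: float = 5.725e12  # cells per kg sediment

    def __post_init__(self) -> None:
        if not self.q_aerobic > self.q_anaerobic > 0:
            raise ConfigurationError("expected q_aerobic > q_anaerobic > 0")
        if self.abundance < 0:
            raise ConfigurationError("abundance must be non-negative")

    def q(self, condition: Condition) -> float:
        if condition == "aerobic":
            return self.q_aerobic
        if condition == "anaerobic":
            return self.q_anaerobic
        raise ConfigurationError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class HeatingRatePrediction:
    """Loss-free heating-rate prediction over a heat-capacity range.

    ``rate_range`` is (low, high) in °C h⁻¹, with the low rate at the high
    end of the ``c_s`` range and vice versa.
    """

    power_density: float  # W kg⁻¹
    rate_range: tuple[float, float]  # °C h⁻¹
    condition: Condition
    c_s_range: tuple[float, float] = DEFAULT_CS_RANGE


@dataclass(frozen=True)
class DryingSeries:
    """Oven-drying mass series for one sediment subsample.

    ``readings`` are (time marker, gross mass in g) pairs recorded until the
    mass stops changing; ``tare_mass`` is the dish mass.
    """

    sample_id: str
    tare_mass: float
    readings: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.readings) < 2:
            raise ConfigurationError("need at least 2 drying readings")
        if self.tare_mass >= self.readings[0][1]:
            raise ConfigurationError("tare mass must be below the first gross mass")

    @property
    def net_masses(self) -> list[float]:
        return [gross - self.tare_mass for _, gross in self.readings]


@dataclass(frozen=True)
class WaterContentResult:
    dry_fraction: float
    water_fraction: float
    converged_at: int  # index of the reading taken as fully dry


def mixture_heat_capacity(
    water_mass_fraction: float,
    c_dry: float,
    c_water: float = SPECIFIC_HEAT_WATER,
) -> float:
    """Mass-weighted heat capacity of a water/dry-solid mixture, J kg⁻¹ °C⁻¹."""
    if not 0.0 <= water_mass_fraction <= 1.0:
        raise ConfigurationError("water_mass_fraction must lie in [0, 1]")
    if c_dry <= 0 or c_water <= 0:
        raise ConfigurationError("heat capacities must be positive")
    w = water_mass_fraction
    return w * c_water + (1.0 - w) * c_dry


def heating_rate(power_density: float, c_s: float) -> float:
    """Loss-free sediment heating rate in °C h⁻¹.

    ``power_density`` in W kg⁻¹, ``c_s`` in J kg⁻¹ °C⁻¹.
    """
    if c_s <= 0:
        raise ConfigurationError("c_s must be positive")
    if power_density < 0:
        raise ConfigurationError("power density must be non-negative")
    return power_density / c_s * 3600.0


def power_density(spec: CellHeatSpec, condition: Condition) -> float:
    """Volumetric metabolic power density q · abundance, W per kg sediment."""
    return spec.q(condition) * spec.abundance


def predict_heating_rates(
    spec: CellHeatSpec = CellHeatSpec(),
    condition: Condition = "aerobic",
    c_s_range: tuple[float, float] = DEFAULT_CS_RANGE,
) -> HeatingRatePrediction:
    """Heating-rate range for a condition over a heat-capacity range."""
    p = power_density(spec, condition)
    low = heating_rate(p, c_s_range[1])
    high = heating_rate(p, c_s_range[0])
    return HeatingRatePrediction(
        power_density=p, rate_range=(low, high), condition=condition, c_s_range=c_s_range
    )


def aerobic_anaerobic_gap(
    aerobic: HeatingRatePrediction, anaerobic: HeatingRatePrediction
) -> tuple[float, float]:
    """Element-wise aerobic-minus-anaerobic heating-rate range, °C h⁻¹.

    This is the idealized hourly top-to-bottom temperature contrast when the
    upper sediment respires aerobically while the lower ferments.
    """
    if aerobic.c_s_range != anaerobic.c_s_range:
        raise ConfigurationError("predictions must share the same c_s range")
    a, b = aerobic.rate_range, anaerobic.rate_range
    return (a[0] - b[0], a[1] - b[1])


def water_content_from_drying(
    series: DryingSeries, convergence_delta: float = 0.01
) -> WaterContentResult:
    """Gravimetric water content from an oven-drying mass series.

    The sample counts as fully dry at the first reading whose change from
    the previous reading is at most ``convergence_delta`` grams.  Returns the
    dry-to-fresh mass ratio and its complement, the water mass fraction.
    """
    net = series.net_masses
    last_delta = None
    for i in range(1, len(net)):
        last_delta = abs(net[i] - net[i - 1])
        if last_delta <= convergence_delta:
            dry = net[i] / net[0]
            return WaterContentResult(
                dry_fraction=dry, water_fraction=1.0 - dry, converged_at=i
            )
    raise NonConvergenceError(
        f"drying series {series.sample_id!r} never converged "
        f"(last mass change {last_delta:.4g} g > {convergence_delta} g)",
        last_delta=last_delta,
    )


def prediction_report(
    spec: CellHeatSpec = CellHeatSpec(),
    c_s_range: tuple[float, float] = DEFAULT_CS_RANGE,
    reference_bounds: dict[str, tuple[float, float]] | None = None,
) -> dict:
    """Tabulate both conditions' predictions and flag reference mismatches.

    Compares the computed rate bounds, rounded to 1 decimal (print
    precision), against ``reference_bounds`` and lists every bound that
    disagrees — the configured references come from an independent
    derivation and do not all match this module's arithmetic at the last
    printed digit.
    """
    if reference_bounds is None:
        reference_bounds = REFERENCE_RATE_BOUNDS
    rows = {}
    discrepancies = []
    for condition in ("aerobic", "anaerobic"):
        pred = predict_heating_rates(spec, condition, c_s_range)  # type: ignore[arg-type]
        rows[condition] = pred
        ref = reference_bounds.get(condition)
        if ref is None:
            continue
        for name, computed, expected in (
            ("low", pred.rate_range[0], ref[0]),
            ("high", pred.rate_range[1], ref[1]),
        ):
            if abs(round(computed, 1) - expected) > 1e-9:
                discrepancies.append(
                    f"{condition} {name} bound: computed {computed:.2f} °C/h "
                    f"(prints {computed:.1f}) vs reference {expected}"
                )
    gap = aerobic_anaerobic_gap(rows["aerobic"], rows["anaerobic"])
    return {"predictions": rows, "gap_range": gap, "discrepancies": discrepancies}


#: Default per-cell heat rates / abundance for the reference model organism.
DEFAULT_CELL_HEAT = CellHeatSpec()
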