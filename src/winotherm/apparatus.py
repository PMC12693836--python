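"""Physical setup constants and arithmetic for the instrumented columns.

The experimental apparatus is a pair of sealed sediment columns (one living,
one autoclaved control) standing in an illuminated incubator, each carrying
two embedded digital thermometers (top and bottom sediment region).  This
module holds the geometry, illumination, and sensor specifications plus the
small arithmetic used to derive reported setup quantities (fill heights,
total photon flux, mean irradiance, sensor quantization step).

Units are fixed per field (cm, mL, m, µmol, °C); no general unit system is
implemented.  Raw operations never round — print-precision rounding is the
caller's concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError, InvalidGeometryError

__all__ = [
    "ColumnGeometry",
    "IlluminationSpec",
    "SensorSpec",
    "fill_height",
    "total_photon_flux",
    "mean_irradiance",
    "quantization_step",
    "PAPER_GEOMETRY",
    "DEFAULT_ILLUMINATION",
    "DS18B20",
]


@dataclass(frozen=True)
class ColumnGeometry:
    """Cylindrical column geometry.

    Parameters
    ----------
    inner_diameter : float
        Inner diameter of the cylinder in cm.
    height : float
        Cylinder height in cm.
    fill_volume : float
        Total sediment fill in mL.
    enriched_volume : float
        Volume of the enriched bottom slurry layer in mL.
    """

    inner_diameter: float
    height: float
    fill_volume: float
    enriched_volume: float

    def __post_init__(self) -> None:
        if min(self.inner_diameter, self.height, self.fill_volume) <= 0:
            raise InvalidGeometryError("diameter, height and fill volume must be positive")
        if self.enriched_volume < 0 or self.enriched_volume > self.fill_volume:
            raise InvalidGeometryError("enriched_volume must lie in [0, fill_volume]")
        if self.fill_volume > self.cross_section_cm2 * self.height:
            raise InvalidGeometryError("fill volume exceeds cylinder capacity")

    @property
    def cross_section_cm2(self) -> float:
        """Cross-sectional area in cm² (1 mL == 1 cm³)."""
        return math.pi * (self.inner_diameter / 2.0) ** 2


# 24 h illumination program: breakpoints (hour of day, intensity fraction),
# linearly interpolated.  The default mirrors an 18 h light / 6 h dark cycle
# with a dim "moonlight" night level and 1 h dawn/dusk ramps.
_DEFAULT_LIGHT_SCHEDULE = (
    (0.0, 1.0),
    (1.0, 0.019),
    (7.0, 0.019),
    (8.0, 1.0),
    (24.0, 1.0),
)


@dataclass(frozen=True)
class IlluminationSpec:
    """Incubator lighting: identical LED lamps over a rectangular footprint."""

    lamp_count: int = 3
    photon_flux_per_lamp: float = 43.91  # µmol s⁻¹
    footprint_length: float = 0.72  # m
    footprint_width: float = 0.55  # m
    schedule: tuple[tuple[float, float], ...] = field(default=_DEFAULT_LIGHT_SCHEDULE)

    def __post_init__(self) -> None:
        if self.lamp_count < 1:
            raise ConfigurationError("lamp_count must be >= 1")
        if self.photon_flux_per_lamp <= 0:
            raise ConfigurationError("photon flux must be positive")
        hours = [h for h, _ in self.schedule]
        fracs = [f for _, f in self.schedule]
        if hours != sorted(hours) or hours[0] != 0.0 or hours[-1] != 24.0:
            raise ConfigurationError("schedule breakpoints must span 0..24 h in order")
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigurationError("intensity fractions must lie in [0, 1]")

    def intensity(self, hour_of_day: float) -> float:
        """Intensity fraction at a clock time (hours, may be fractional)."""
        h = hour_of_day % 24.0
        pts = self.schedule
        for (h0, f0), (h1, f1) in zip(pts, pts[1:]):
            if h0 <= h <= h1:
                if h1 == h0:
                    return f1
                return f0 + (f1 - f0) * (h - h0) / (h1 - h0)
        return pts[-1][1]


@dataclass(frozen=True)
class SensorSpec:
    """Digital thermometer characteristics (resolution vs. accuracy).

    ``resolution`` is the least-significant quantization step in °C;
    ``accuracy`` the manufacturer's absolute error bound.  The two are
    distinct: consistent differences well below the ±accuracy band are still
    meaningful when they exceed the quantization step.
    """

    resolution: float = 0.0625
    accuracy: float = 0.5
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        if self.accuracy < self.resolution:
            raise ConfigurationError("accuracy cannot be finer than resolution")


def fill_height(volume_ml: float, geometry: ColumnGeometry) -> float:
    """Height (cm) a sediment volume (mL) reaches in the column.

    Pure cylinder arithmetic ``V / (π r²)``; the caller decides whether the
    result is a layer height or a cumulative fill height.
    """
    if volume_ml < 0:
        raise InvalidGeometryError("volume must be non-negative")
    return volume_ml / geometry.cross_section_cm2


def total_photon_flux(spec: IlluminationSpec) -> float:
    """Total photon flux of all lamps in µmol s⁻¹."""
    return spec.lamp_count * spec.photon_flux_per_lamp


def mean_irradiance(spec: IlluminationSpec) -> float:
    """Average photon irradiance over the footprint, µmol m⁻² s⁻¹."""
    area = spec.footprint_length * spec.footprint_width
    if area <= 0:
        raise InvalidGeometryError("footprint area must be positive")
    return total_photon_flux(spec) / area


def quantization_step(bit_depth: int) -> float:
    """Temperature quantization step (°C) of the sensor family at a bit depth.

    The converter dedicates ``bit_depth - 8`` bits to the fractional part,
    giving a step of ``2**-(bit_depth - 8)`` °C; supported depths are 9–12.
    """
    if bit_depth not in (9, 10, 11, 12):
        raise ConfigurationError(f"unsupported bit depth {bit_depth}; supported: 9-12")
    return 2.0 ** -(bit_depth - 8)


#: Column geometry of the reference setup (4 cm ID, 20 cm tall, 200 mL fill
#: of which the bottom 50 mL is the enriched slurry).
PAPER_GEOMETRY = ColumnGeometry(
    inner_diameter=4.0, height=20.0, fill_volume=200.0, enriched_volume=50.0
)

#: Reference illumination: 3 × 43.91 µmol s⁻¹ lamps over a 72 × 55 cm footprint.
DEFAULT_ILLUMINATION = IlluminationSpec()

#: The embedded digital thermometer at its default 12-bit setting.
DS18B20 = SensorSpec(resolution=0.0625, accuracy=0.5, bit_depth=12)
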