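"""Lithotripsy-duration estimation from segmented stone volume.

The structural model is ``duration = volume / ablation_rate`` where the
ablation rate (mm^3/s) depends on the laser source, its pulse settings,
the fiber diameter and the stone composition.  Rates are supplied by the
user as a calibration table (JSON); no calibration ships enabled, because
published ablation speeds vary widely across lasers, compositions and
in-vitro protocols.  An example table with clearly illustrative values is
bundled for tests and demos only (``lithovol/data/example_rates.json``).

Lookup is exact: a missing (laser, fiber, composition, energy, frequency)
key raises rather than silently substituting a nearest match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "LaserSettings",
    "AblationRateTable",
    "LDEstimate",
    "estimate_ld",
    "LASER_SOURCES",
]

LASER_SOURCES = ("HoYAG", "HoYAG_MOSES", "TFL")


class CalibrationError(KeyError):
    """No ablation-rate calibration for the requested settings."""


@dataclass(frozen=True)
class LaserSettings:
    """One lithotripsy configuration.

    pulse_energy_J and frequency_Hz are the laser pulse settings; their
    product is the average power in watts.
    """

    laser_source: str
    fiber_diameter_um: float
    composition: str
    pulse_energy_J: float
    frequency_Hz: float

    def __post_init__(self) -> None:
        if self.laser_source not in LASER_SOURCES:
            raise ValueError(
                f"laser_source must be one of {LASER_SOURCES}, got {self.laser_source!r}"
            )
        for name in ("fiber_diameter_um", "pulse_energy_J", "frequency_Hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def power_W(self) -> float:
        return self.pulse_energy_J * self.frequency_Hz

    def key(self) -> tuple:
        return (
            self.laser_source,
            float(self.fiber_diameter_um),
            self.composition,
            float(self.pulse_energy_J),
            float(self.frequency_Hz),
        )


class AblationRateTable:
    """Calibration mapping laser settings to ablation speed (mm^3/s)."""

    def __init__(self, entries: dict[tuple, float]):
        for key, speed in entries.items():
            if speed <= 0:
                raise ValueError(f"ablation speed must be positive, got {speed} for {key}")
        self._entries = dict(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(self, settings: LaserSettings) -> float:
        try:
            return self._entries[settings.key()]
        except KeyError:
            raise CalibrationError(
                f"no ablation-rate calibration for {settings}; "
                "add an entry to the rate table (nearest-match is never applied)"
            ) from None

    @classmethod
    def from_json(cls, path: str | Path) -> "AblationRateTable":
        """Load a rate table from JSON.

        Schema: ``{"entries": [{"laser_source": ..., "fiber_diameter_um": ...,
        "composition": ..., "pulse_energy_J": ..., "frequency_Hz": ...,
        "ablation_speed_mm3_per_s": ...}, ...]}``.
        """
        with open(path) as fh:
            doc = json.load(fh)
        entries: dict[tuple, float] = {}
        for row in doc["entries"]:
            settings = LaserSettings(
                laser_source=row["laser_source"],
                fiber_diameter_um=row["fiber_diameter_um"],
                composition=row["composition"],
                pulse_energy_J=row["pulse_energy_J"],
                frequency_Hz=row["frequency_Hz"],
            )
            entries[settings.key()] = float(row["ablation_speed_mm3_per_s"])
        return cls(entries)


@dataclass(frozen=True)
class LDEstimate:
    """Estimated lithotripsy duration, with inputs echoed for audit."""

    duration_s: float
    power_W: float
    volume_mm3: float
    ablation_speed_mm3_per_s: float
    settings: LaserSettings

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0


def estimate_ld(
    volume_mm3: float, settings: LaserSettings, table: AblationRateTable
) -> LDEstimate:
    """Estimate lithotripsy duration as volume / ablation rate.

    Linear in volume and deterministic; raises ``CalibrationError`` when the
    settings are absent from the table.
    """
    if volume_mm3 < 0:
        raise ValueError("volume must be non-negative")
    speed = table.lookup(settings)
    return LDEstimate(
        duration_s=float(volume_mm3) / speed,
        power_W=settings.power_W,
        volume_mm3=float(volume_mm3),
        ablation_speed_mm3_per_s=speed,
        settings=settings,
    )
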