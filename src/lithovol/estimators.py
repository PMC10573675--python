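"""Classical geometric stone-burden estimators.

These closed-form approximations are what volumetric segmentation is
usually compared against: the sphere formula 4/3*pi*r^3 applied to the
maximum diameter, the scalene-ellipsoid formula pi/6*l*w*h, Ackermann's
formula 0.6*pi*r^2, the cumulative diameter, and the elliptical surface
area d*w*pi/4.

Note on Ackermann's formula: as conventionally printed it is dimensionally
an area (mm^2 for a radius in mm), not a volume.  It is implemented verbatim
here; treat its output as the historical index it is rather than a physical
volume.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

__all__ = [
    "sphere_volume",
    "ellipsoid_volume",
    "ackerman_volume",
    "cumulative_diameter",
    "surface_area_estimate",
]


def _check_nonnegative(name: str, value: float) -> float:
    value = float(value)
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    return value


def sphere_volume(diameter_mm: float) -> float:
    """Volume of a sphere from its diameter: 4/3 * pi * (d/2)^3, in mm^3."""
    d = _check_nonnegative("diameter", diameter_mm)
    return 4.0 / 3.0 * math.pi * (d / 2.0) ** 3


def ellipsoid_volume(length_mm: float, width_mm: float, height_mm: float) -> float:
    """Scalene ellipsoid volume from the three axis diameters: pi/6*l*w*h."""
    l = _check_nonnegative("length", length_mm)
    w = _check_nonnegative("width", width_mm)
    h = _check_nonnegative("height", height_mm)
    return math.pi / 6.0 * l * w * h


def ackerman_volume(radius_mm: float) -> float:
    """Ackermann's stone-burden formula, 0.6 * pi * r^2, exactly as printed.

    Dimensionally an area; see the module docstring.
    """
    r = _check_nonnegative("radius", radius_mm)
    return 0.6 * math.pi * r**2


def cumulative_diameter(diameters_mm: Iterable[float]) -> float:
    """Sum of the largest stone diameters over all planes/stones (mm).

    An empty sequence sums to 0.
    """
    total = 0.0
    for d in diameters_mm:
        total += _check_nonnegative("diameter", d)
    return total


def surface_area_estimate(max_diameter_mm: float, width_mm: float) -> float:
    """Elliptical surface-area estimate: max diameter * width * pi/4, mm^2."""
    d = _check_nonnegative("max_diameter", max_diameter_mm)
    w = _check_nonnegative("width", width_mm)
    return d * w * math.pi / 4.0
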