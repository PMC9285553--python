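"""Temperature-referenced water self-diffusivity.

The accuracy analysis compares measured mean diffusivity in the 0% PVP tube
against the self-diffusion coefficient of water at the bath temperature
(0 degC for an ice-water bath).  The reference is obtained by a
second-order polynomial fit to literature self-diffusion measurements
(Mills 1973, tracer technique, 1-45 degC) evaluated at the requested
temperature.  The literature table ships with the package as a citable CSV
fixture; the 0 degC value is always computed from the fit, never hard-coded.

Units are mm^2/s internally; the fixture stores 1e-9 m^2/s (= 1e-3 mm^2/s).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "ReferenceDiffusivity",
    "load_mills_table",
    "fit_reference_poly",
    "dref_at",
    "fractional_sensitivity",
    "water_reference",
]

_MILLS_RESOURCE = "mills1973_water_self_diffusion.csv"


@dataclass(frozen=True)
class ReferenceDiffusivity:
    """A fitted reference: D(T) = c0 + c1*T + c2*T^2, evaluated at one T."""

    temperature: float  # degC
    d_ref: float  # mm^2/s
    poly_coeffs: tuple[float, float, float]  # (c0, c1, c2)
    source_points: tuple[tuple[float, float], ...]  # (degC, mm^2/s)

    def __post_init__(self) -> None:
        if self.d_ref <= 0:
            raise ValueError("reference diffusivity must be positive")
        if len(self.source_points) < 3:
            raise ValueError("at least three source points required")


def load_mills_table() -> list[tuple[float, float]]:
    """(temperature degC, diffusivity mm^2/s) pairs from the bundled table."""
    points = []
    with resources.files("dtiphantom.data").joinpath(_MILLS_RESOURCE).open() as fh:
        for row in csv.DictReader(fh):
            points.append(
                (float(row["temperature_C"]), float(row["diffusivity_1e-9_m2_per_s"]) * 1e-3)
            )
    return points


def fit_reference_poly(points) -> tuple[float, float, float]:
    """Least-squares quadratic D(T) = c0 + c1*T + c2*T^2.

    Requires at least three distinct temperatures.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("points must be (temperature, diffusivity) pairs")
    temps, diffs = pts[:, 0], pts[:, 1]
    if np.unique(temps).size < 3:
        raise ValueError("at least three distinct temperatures required")
    c2, c1, c0 = np.polyfit(temps, diffs, 2)
    return float(c0), float(c1), float(c2)


def dref_at(
    poly_coeffs,
    temperature: float,
    fitted_range: tuple[float, float] | None = None,
) -> float:
    """Evaluate the fitted quadratic at a temperature (mm^2/s).

    Warns when extrapolating more than 5 degC beyond the fitted range.
    """
    c0, c1, c2 = poly_coeffs
    if fitted_range is not None:
        lo, hi = fitted_range
        if temperature < lo - 5.0 or temperature > hi + 5.0:
            warnings.warn(
                f"evaluating the reference fit at {temperature} degC, more than 5 degC "
                f"outside the fitted range [{lo}, {hi}]"
            )
    return float(c0 + c1 * temperature + c2 * temperature**2)


def fractional_sensitivity(poly_coeffs, temperature: float) -> float:
    """(dD/dT)/D at a temperature, as a fraction per degC."""
    c0, c1, c2 = poly_coeffs
    d = c0 + c1 * temperature + c2 * temperature**2
    return float((c1 + 2.0 * c2 * temperature) / d)


def water_reference(temperature: float = 0.0) -> ReferenceDiffusivity:
    """Reference water diffusivity at a temperature from the bundled table."""
    points = load_mills_table()
    coeffs = fit_reference_poly(points)
    temps = [t for t, _ in points]
    d = dref_at(coeffs, temperature, fitted_range=(min(temps), max(temps)))
    return ReferenceDiffusivity(
        temperature=float(temperature),
        d_ref=d,
        poly_coeffs=coeffs,
        source_points=tuple(points),
    )
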