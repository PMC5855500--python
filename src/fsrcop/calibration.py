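"""FSR voltage-to-force calibration.

Each FSR channel maps its acquisition-chain voltage to force through a
fourth-order polynomial, force(v) = c0 + c1 v + c2 v^2 + c3 v^3 + c4 v^4,
evaluated by Horner's scheme and floored at 0 N (a resistive sensor cannot
report a negative force). Polynomials are per-sensor configuration inputs;
:data:`DEFAULT_CALIBRATION_COEFFS` is a synthetic, non-physical default
shipped for simulation and demos only.

Out-of-range voltages are clamped to the calibration's valid range with a
logged warning rather than raised, because transient spikes are expected
from real acquisition chains.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationPoly",
    "CalibrationError",
    "voltage_to_force",
    "fit_calibration",
    "apply_calibration",
    "load_calibration",
    "save_calibration",
    "DEFAULT_CALIBRATION_COEFFS",
]

logger = logging.getLogger(__name__)

#: Synthetic default quartic (N as a function of volts on a 0-3.3 V chain).
#: Monotone increasing on [0, 3.3]; for simulation/demo use only.
DEFAULT_CALIBRATION_COEFFS = (0.0, 4.0, 3.0, 0.8, 0.12)


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs (too few points, degeneracy)."""


@dataclass(frozen=True)
class CalibrationPoly:
    """A per-sensor voltage -> force polynomial.

    ``coefficients`` are ascending powers (c0..c4 for the default quartic);
    ``valid_range`` is the voltage interval the fit is trusted on.
    ``residual_rms`` is the RMS of the training residuals when the
    polynomial came from :func:`fit_calibration` (None for hand-specified
    polynomials).
    """

    sensor_id: int
    coefficients: tuple[float, ...]
    valid_range: tuple[float, float]
    residual_rms: float | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) < 1:
            raise CalibrationError("polynomial needs at least one coefficient")
        lo, hi = self.valid_range
        if not lo < hi:
            raise CalibrationError(
                f"sensor {self.sensor_id}: valid_range [{lo}, {hi}] must satisfy lo < hi"
            )


def voltage_to_force(v, poly: CalibrationPoly):
    """Evaluate a calibration polynomial at voltage(s) ``v``.

    Voltages outside ``poly.valid_range`` are clamped (with a warning);
    the polynomial value is floored at 0 N. Accepts scalars or arrays and
    returns the matching shape.
    """
    arr = np.asarray(v, dtype=float)
    lo, hi = poly.valid_range
    if np.any(arr < lo) or np.any(arr > hi):
        logger.warning(
            "sensor %d: %d voltage sample(s) outside [%g, %g] V clamped",
            poly.sensor_id,
            int(np.sum((arr < lo) | (arr > hi))),
            lo,
            hi,
        )
        arr = np.clip(arr, lo, hi)
    # polyval evaluates ascending-order coefficients with Horner's scheme
    force = np.polynomial.polynomial.polyval(arr, np.asarray(poly.coefficients))
    force = np.maximum(force, 0.0)
    return float(force) if np.isscalar(v) else force


def fit_calibration(pairs, sensor_id: int = 0, degree: int = 4) -> CalibrationPoly:
    """Least-squares polynomial fit of bench (voltage, force) pairs.

    Requires at least ``degree + 1`` distinct voltages. The returned
    polynomial records the training residual RMS and a valid range equal to
    the span of the calibration voltages.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise CalibrationError("pairs must be an (n, 2) array of (voltage, force)")
    v, f = pairs[:, 0], pairs[:, 1]
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(f))):
        raise CalibrationError("non-finite calibration pair")
    n_distinct = np.unique(v).size
    if n_distinct < degree + 1:
        raise CalibrationError(
            f"need at least {degree + 1} distinct voltages for degree {degree}, "
            f"got {n_distinct}"
        )
    vander = np.vander(v, degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(vander, f, rcond=None)
    if rank < degree + 1:
        raise CalibrationError(
            f"degenerate Vandermonde system (rank {rank} < {degree + 1}); "
            "calibration voltages are numerically collinear"
        )
    resid = vander @ coef - f
    rms = float(np.sqrt(np.mean(resid**2)))
    return CalibrationPoly(
        sensor_id=sensor_id,
        coefficients=tuple(float(c) for c in coef),
        valid_range=(float(v.min()), float(v.max())),
        residual_rms=rms,
    )


def apply_calibration(voltages, polys) -> np.ndarray:
    """Convert an (m, 12) voltage array to forces, channel by channel."""
    volts = np.asarray(voltages, dtype=float)
    if volts.ndim != 2 or volts.shape[1] != len(polys):
        raise CalibrationError(
            f"voltage array shape {volts.shape} does not match {len(polys)} polynomials"
        )
    out = np.empty_like(volts)
    for i, poly in enumerate(polys):
        out[:, i] = voltage_to_force(volts[:, i], poly)
    return out


def save_calibration(polys, path) -> None:
    doc = {
        "sensors": [
            {
                "id": p.sensor_id,
                "coefficients": list(p.coefficients),
                "valid_range": list(p.valid_range),
                "residual_rms": p.residual_rms,
            }
            for p in polys
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_calibration(path) -> list[CalibrationPoly]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if "sensors" not in doc:
        raise CalibrationError("calibration JSON must contain a 'sensors' array")
    polys = []
    for k, entry in enumerate(doc["sensors"]):
        for key in ("id", "coefficients", "valid_range"):
            if key not in entry:
                raise CalibrationError(f"sensors[{k}]: missing field '{key}'")
        polys.append(
            CalibrationPoly(
                sensor_id=int(entry["id"]),
                coefficients=tuple(float(c) for c in entry["coefficients"]),
                valid_range=(
                    float(entry["valid_range"][0]),
                    float(entry["valid_range"][1]),
                ),
                residual_rms=entry.get("residual_rms"),
            )
        )
    return polys


def default_calibration(n_sensors: int = 12) -> list[CalibrationPoly]:
    """Per-sensor copies of the synthetic default quartic (simulation only)."""
    return [
        CalibrationPoly(
            sensor_id=i + 1,
            coefficients=DEFAULT_CALIBRATION_COEFFS,
            valid_range=(0.0, 3.3),
        )
        for i in range(n_sensors)
    ]
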