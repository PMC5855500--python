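"""Insole coordinate frame and the 12-sensor layout.

The insole frame follows the instrumented-insole convention: the x-axis is
the tangent line to the bottom (posterior) edge of the insole and measures
the medial-lateral (ML) position in mm; the y-axis is the tangent line to
the left edge and measures the anterior-posterior (AP) position in mm. The
origin sits at the intersection of the two tangents, so all coordinates are
non-negative and COP trajectories live in the same frame and unit.

The shipped default layout is a configuration artifact: it places twelve
12.7 mm FSR sensing discs over the load-bearing regions of a US-9 foot
(great toe, lesser toes, the five metatarsal heads, midfoot/arch and heel).
Every downstream operation takes the layout as an explicit parameter, so
alternative layouts (other insoles, mirrored right feet) are first-class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Sensor",
    "SensorLayout",
    "LayoutError",
    "default_layout",
    "load_layout",
    "save_layout",
]

N_SENSORS = 12
DEFAULT_SENSING_DIAMETER = 12.7  # mm, FSR-402 style sensing disc
DEFAULT_BOUNDING_BOX = (100.0, 280.0)  # mm (ML width, AP length) for a US 9 insole


class LayoutError(ValueError):
    """Raised when a sensor layout violates its schema or invariants."""


@dataclass(frozen=True)
class Sensor:
    """One FSR position in the insole frame (mm)."""

    sensor_id: int
    x: float
    y: float
    sensing_diameter: float = DEFAULT_SENSING_DIAMETER


@dataclass(frozen=True)
class SensorLayout:
    """Twelve uniquely-identified sensors in the insole frame.

    Invariants (checked on construction): exactly 12 sensors with distinct
    ids 1..12, non-negative coordinates, all inside ``bounding_box``.
    """

    sensors: tuple[Sensor, ...]
    insole_size: str = "US9"
    bounding_box: tuple[float, float] = DEFAULT_BOUNDING_BOX
    name: str = field(default="default")

    def __post_init__(self) -> None:
        if len(self.sensors) != N_SENSORS:
            raise LayoutError(
                f"expected {N_SENSORS} sensors, found {len(self.sensors)}"
            )
        ids = [s.sensor_id for s in self.sensors]
        if sorted(ids) != list(range(1, N_SENSORS + 1)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            if dupes:
                raise LayoutError(f"duplicate sensor_id(s): {dupes}")
            raise LayoutError(f"sensor ids must be 1..{N_SENSORS}, got {sorted(ids)}")
        bx, by = self.bounding_box
        for s in self.sensors:
            if s.x < 0 or s.y < 0:
                raise LayoutError(
                    f"sensor {s.sensor_id}: negative coordinate ({s.x}, {s.y})"
                )
            if s.x > bx or s.y > by:
                raise LayoutError(
                    f"sensor {s.sensor_id}: ({s.x}, {s.y}) outside "
                    f"{bx} x {by} mm bounding box"
                )

    @property
    def coords(self) -> np.ndarray:
        """(12, 2) array of (x, y) positions ordered by sensor_id."""
        ordered = sorted(self.sensors, key=lambda s: s.sensor_id)
        return np.array([[s.x, s.y] for s in ordered], dtype=float)

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]


# Nominal positions (mm) of the default US-9 layout, ordered by sensor id:
# 1 great toe, 2 lesser toes, 3-7 metatarsal heads I-V, 8 medial arch,
# 9 lateral midfoot, 10 medial heel, 11 lateral heel, 12 heel centre.
_DEFAULT_POSITIONS: tuple[tuple[float, float], ...] = (
    (35.0, 242.0),
    (62.0, 228.0),
    (30.0, 188.0),
    (44.0, 196.0),
    (57.0, 192.0),
    (69.0, 183.0),
    (80.0, 170.0),
    (38.0, 130.0),
    (68.0, 120.0),
    (42.0, 55.0),
    (64.0, 55.0),
    (53.0, 30.0),
)


def default_layout() -> SensorLayout:
    """The shipped 12-sensor US-9 layout.

    Covers great toe, lesser toes, metatarsophalangeal region, arch/midfoot
    and heel. The numeric coordinates are a shipped configuration default,
    not a measurement.
    """
    sensors = tuple(
        Sensor(sensor_id=i + 1, x=x, y=y) for i, (x, y) in enumerate(_DEFAULT_POSITIONS)
    )
    return SensorLayout(sensors=sensors)


def save_layout(layout: SensorLayout, path) -> None:
    """Write a layout to JSON (lossless round-trip with :func:`load_layout`)."""
    doc = {
        "insole_size": layout.insole_size,
        "bounding_box": list(layout.bounding_box),
        "name": layout.name,
        "sensors": [
            {
                "id": s.sensor_id,
                "x": s.x,
                "y": s.y,
                "sensing_diameter": s.sensing_diameter,
            }
            for s in layout.sensors
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_layout(path) -> SensorLayout:
    """Read a layout JSON, validating the schema field-by-field."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise LayoutError(f"malformed layout JSON: {exc}") from exc
    if not isinstance(doc, dict) or "sensors" not in doc:
        raise LayoutError("layout JSON must be an object with a 'sensors' array")
    raw = doc["sensors"]
    if not isinstance(raw, list):
        raise LayoutError("'sensors' must be an array")
    sensors = []
    for k, entry in enumerate(raw):
        for key in ("id", "x", "y"):
            if key not in entry:
                raise LayoutError(f"sensors[{k}]: missing field '{key}'")
        sensors.append(
            Sensor(
                sensor_id=int(entry["id"]),
                x=float(entry["x"]),
                y=float(entry["y"]),
                sensing_diameter=float(
                    entry.get("sensing_diameter", DEFAULT_SENSING_DIAMETER)
                ),
            )
        )
    bbox = tuple(doc.get("bounding_box", DEFAULT_BOUNDING_BOX))
    return SensorLayout(
        sensors=tuple(sensors),
        insole_size=str(doc.get("insole_size", "US9")),
        bounding_box=(float(bbox[0]), float(bbox[1])),
        name=str(doc.get("name", "default")),
    )
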