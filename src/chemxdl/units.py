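"""Quantities and unit parsing for the XDL dialect.

Seven physical dimensions are recognised (volume, mass, amount,
temperature, time, pressure, rotation-rate), each with a small closed set
of accepted unit spellings.  Temperature is Celsius-only by design:
Kelvin inputs are reported as unit errors rather than silently converted,
because silent conversion bugs in procedure translation are exactly the
failure mode the validator exists to catch.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Tuple

DIMENSIONS = (
    "volume",
    "mass",
    "amount",
    "temperature",
    "time",
    "pressure",
    "rotation-rate",
)

#: canonical base unit per dimension
BASE_UNITS: Dict[str, str] = {
    "volume": "mL",
    "mass": "g",
    "amount": "mol",
    "temperature": "°C",
    "time": "s",
    "pressure": "mbar",
    "rotation-rate": "rpm",
}

# canonical unit -> (dimension, multiplicative factor to base unit)
_CANONICAL: Dict[str, Tuple[str, float]] = {
    "mL": ("volume", 1.0),
    "L": ("volume", 1000.0),
    "µL": ("volume", 1e-3),
    "g": ("mass", 1.0),
    "mg": ("mass", 1e-3),
    "kg": ("mass", 1e3),
    "mol": ("amount", 1.0),
    "mmol": ("amount", 1e-3),
    "°C": ("temperature", 1.0),
    "s": ("time", 1.0),
    "min": ("time", 60.0),
    "h": ("time", 3600.0),
    "mbar": ("pressure", 1.0),
    "bar": ("pressure", 1000.0),
    "rpm": ("rotation-rate", 1.0),
}

# accepted spelling (lower-cased, internal spaces removed) -> canonical unit
UNIT_ALIASES: Dict[str, str] = {
    "ml": "mL",
    "l": "L",
    "liter": "L",
    "litre": "L",
    "µl": "µL",
    "ul": "µL",
    "g": "g",
    "gram": "g",
    "grams": "g",
    "mg": "mg",
    "kg": "kg",
    "mol": "mol",
    "mmol": "mmol",
    "°c": "°C",
    "c": "°C",
    "degc": "°C",
    "celsius": "°C",
    "s": "s",
    "sec": "s",
    "secs": "s",
    "second": "s",
    "seconds": "s",
    "min": "min",
    "mins": "min",
    "minute": "min",
    "minutes": "min",
    "h": "h",
    "hr": "h",
    "hrs": "h",
    "hour": "h",
    "hours": "h",
    "mbar": "mbar",
    "bar": "bar",
    "rpm": "rpm",
}


class UnitError(ValueError):
    """Unparseable quantity text or a unit of the wrong dimension."""

    def __init__(self, message: str, text: str):
        super().__init__(message)
        self.text = text


@dataclass(frozen=True)
class Quantity:
    """A magnitude with a canonical unit symbol and its dimension."""

    magnitude: float
    unit: str
    dimension: str

    def __post_init__(self) -> None:
        if self.unit not in _CANONICAL:
            raise UnitError(f"unknown unit '{self.unit}'", self.unit)
        dim, _ = _CANONICAL[self.unit]
        if dim != self.dimension:
            raise UnitError(
                f"unit '{self.unit}' is {dim}, not {self.dimension}", self.unit
            )

    def to_base(self) -> float:
        """Magnitude expressed in the dimension's base unit."""
        return self.magnitude * _CANONICAL[self.unit][1]

    @classmethod
    def from_base(cls, dimension: str, value: float) -> "Quantity":
        return cls(value, BASE_UNITS[dimension], dimension)

    def __str__(self) -> str:
        m = self.magnitude
        text = str(int(m)) if float(m).is_integer() and abs(m) < 1e15 else repr(m)
        return f"{text} {self.unit}"


_QTY_RE = re.compile(
    r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*(\S.*?)\s*$"
)


def parse_quantity(text: str, expected_dimension: str) -> Quantity:
    """Parse an attribute string like ``"20 ml"`` into a :class:`Quantity`.

    Accepts the documented spelling variants (case, spacing, ``ml``/``mL``,
    ``°C``/``C``, ``h``/``hr``...).  A unit from another dimension — e.g. a
    time unit where a volume is expected, or Kelvin anywhere — raises
    :class:`UnitError` carrying the offending text.
    """
    if expected_dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension '{expected_dimension}'")
    match = _QTY_RE.match(text or "")
    if not match:
        raise UnitError(f"cannot parse quantity from '{text}'", text)
    magnitude = float(match.group(1))
    unit_text = match.group(2)
    canonical = UNIT_ALIASES.get(unit_text.replace(" ", "").lower())
    if canonical is None:
        raise UnitError(f"unknown unit '{unit_text}' in '{text}'", text)
    dim = _CANONICAL[canonical][0]
    if dim != expected_dimension:
        raise UnitError(
            f"'{text}' has dimension {dim}, expected {expected_dimension}", text
        )
    return Quantity(magnitude, canonical, dim)
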