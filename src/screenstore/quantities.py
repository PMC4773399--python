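"""Unit-bearing scalar values.

Experimental metadata in imaging — exposure times, emission wavelengths,
incubation temperatures — is only meaningful with a unit attached, so every
quantity here carries a symbol from a fixed registry and can be converted
within its dimension.

The registry maps each unit symbol to ``(dimension, factor, offset)`` such
that ``value_in_base_unit = value * factor + offset``.  Conversions go
through the dimension's base unit; for all listed units except the
temperature scales the offset is zero (pure linear scaling).  Temperature
conversions are affine and apply to absolute temperatures only — there is no
temperature-difference type.

Symbols are case-sensitive UTF-8: ``"°C"`` is canonical and bare ``"C"`` is
rejected (it would collide with the coulomb).  The default registry covers
SI base units plus the units common in microscopy acquisition metadata;
chemistry units such as molarity can be merged in from a plain-text table
via :meth:`UnitRegistry.load_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, TextIO

from .errors import DimensionError, QuantityParseError, UnitRegistryError

DIMENSIONS = (
    "length",
    "time",
    "temperature",
    "electric-potential",
    "pressure",
    "frequency",
    "angle",
    "dimensionless",
)

# symbol -> (dimension, factor, offset); base units have factor 1, offset 0.
_DEFAULT_UNITS: dict[str, tuple[str, float, float]] = {
    # length (base: m)
    "m": ("length", 1.0, 0.0),
    "mm": ("length", 1e-3, 0.0),
    "µm": ("length", 1e-6, 0.0),
    "nm": ("length", 1e-9, 0.0),
    # time (base: s)
    "s": ("time", 1.0, 0.0),
    "ms": ("time", 1e-3, 0.0),
    "µs": ("time", 1e-6, 0.0),
    "min": ("time", 60.0, 0.0),
    "h": ("time", 3600.0, 0.0),
    # temperature (base: K); °F: K = (F + 459.67) * 5/9
    "K": ("temperature", 1.0, 0.0),
    "°C": ("temperature", 1.0, 273.15),
    "°F": ("temperature", 5.0 / 9.0, 459.67 * 5.0 / 9.0),
    # electric potential (base: V)
    "V": ("electric-potential", 1.0, 0.0),
    "mV": ("electric-potential", 1e-3, 0.0),
    # pressure (base: Pa)
    "Pa": ("pressure", 1.0, 0.0),
    "bar": ("pressure", 1e5, 0.0),
    # frequency (base: Hz)
    "Hz": ("frequency", 1.0, 0.0),
    "kHz": ("frequency", 1e3, 0.0),
    # angle (base: rad)
    "rad": ("angle", 1.0, 0.0),
    "deg": ("angle", math.pi / 180.0, 0.0),
    # dimensionless
    "": ("dimensionless", 1.0, 0.0),
}

# Aliases accepted on input, normalised to the canonical symbol.
_ALIASES = {"um": "µm", "us": "µs", "degC": "°C", "degF": "°F"}


class UnitRegistry:
    """Registry of unit symbols with affine conversions to a per-dimension base."""

    def __init__(self, units: dict[str, tuple[str, float, float]] | None = None):
        self._units = dict(_DEFAULT_UNITS if units is None else units)

    def __contains__(self, symbol: str) -> bool:
        return self.normalize(symbol) in self._units

    def normalize(self, symbol: str) -> str:
        symbol = symbol.strip()
        return _ALIASES.get(symbol, symbol)

    def lookup(self, symbol: str) -> tuple[str, float, float]:
        sym = self.normalize(symbol)
        try:
            return self._units[sym]
        except KeyError:
            raise UnitRegistryError(f"unknown unit symbol: {symbol!r}") from None

    def dimension(self, symbol: str) -> str:
        return self.lookup(symbol)[0]

    def register(self, symbol: str, dimension: str, factor: float, offset: float = 0.0) -> None:
        if dimension not in DIMENSIONS:
            raise UnitRegistryError(f"unknown dimension: {dimension!r}")
        if symbol != symbol.strip() or (not symbol and dimension != "dimensionless"):
            raise UnitRegistryError(f"bad unit symbol: {symbol!r}")
        self._units[symbol] = (dimension, float(factor), float(offset))

    def symbols(self) -> list[str]:
        return sorted(self._units)

    # -- plain-text (TSV) serialisation so deployments can extend the registry

    def dump_table(self, fh: TextIO) -> None:
        fh.write("symbol\tdimension\tfactor\toffset\n")
        for sym in sorted(self._units):
            dim, factor, offset = self._units[sym]
            fh.write(f"{sym}\t{dim}\t{factor!r}\t{offset!r}\n")

    def load_table(self, fh: TextIO | Iterable[str]) -> int:
        """Merge rows of a ``symbol<TAB>dimension<TAB>factor<TAB>offset`` table.

        Returns the number of symbols registered.
        """
        n = 0
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or (i == 0 and line.startswith("symbol\t")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise UnitRegistryError(f"bad registry row: {line!r}")
            sym, dim, factor, offset = parts
            self.register(sym, dim, float(factor), float(offset))
            n += 1
        return n


#: Shared default registry used when no explicit one is passed.
DEFAULT_REGISTRY = UnitRegistry()


@dataclass(frozen=True)
class Quantity:
    """A finite real value with a registered unit symbol."""

    value: float
    unit: str
    dimension: str

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise QuantityParseError(f"non-finite quantity value: {self.value!r}")


def quantity(value: float, unit: str, registry: UnitRegistry | None = None) -> Quantity:
    """Build a Quantity, resolving *unit* against the registry."""
    reg = registry or DEFAULT_REGISTRY
    dim, _, _ = reg.lookup(unit)
    return Quantity(float(value), reg.normalize(unit), dim)


def convert(q: Quantity, target_unit: str, registry: UnitRegistry | None = None) -> Quantity:
    """Convert *q* to *target_unit* within the same dimension.

    Conversion passes through the dimension's base unit:
    ``base = v * f_src + o_src`` then ``v' = (base - o_dst) / f_dst``.
    """
    reg = registry or DEFAULT_REGISTRY
    src_dim, src_f, src_o = reg.lookup(q.unit)
    dst_dim, dst_f, dst_o = reg.lookup(target_unit)
    if src_dim != dst_dim:
        raise DimensionError(
            f"cannot convert {q.unit!r} ({src_dim}) to {target_unit!r} ({dst_dim})"
        )
    base = q.value * src_f + src_o
    return Quantity((base - dst_o) / dst_f, reg.normalize(target_unit), dst_dim)


def parse_quantity(
    value_text: str, unit_text: str, registry: UnitRegistry | None = None
) -> Quantity:
    """Parse a (value, unit) text pair, e.g. ``("37", "°C")``.

    Whitespace-tolerant on both parts; the unit must be registered.
    """
    try:
        value = float(value_text.strip())
    except (ValueError, AttributeError):
        raise QuantityParseError(f"not a number: {value_text!r}") from None
    if not math.isfinite(value):
        raise QuantityParseError(f"non-finite value: {value_text!r}")
    return quantity(value, unit_text, registry)
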