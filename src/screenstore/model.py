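"""Domain types for the HCS containment hierarchy.

Screen → Plate → Well → Field → Image → Channel, plus Reagent and ROI.
Objects are plain dataclasses; persistence, IDs and referential integrity
live in :mod:`screenstore.store`.  Images reference their pixel bytes
in place: ``pixel_source`` is an external path that is never copied into
the store.

All indices are 0-based internally.  User-facing well labels are the bench
convention letter-row + 1-based column ("A1"); rows past "Z" use double
letters ("AA", "AB", ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from typing import NamedTuple, Optional

from .errors import BoundsError, PlateFormatError

OTYPES = (
    "screen",
    "plate",
    "well",
    "field",
    "image",
    "channel",
    "reagent",
    "roi",
    "annotation",
    "table",
)


class ObjectRef(NamedTuple):
    """The universal handle: an object-type tag plus a non-negative integer ID."""

    otype: str
    oid: int

    def __str__(self) -> str:
        return f"{self.otype}:{self.oid}"

    @classmethod
    def parse(cls, text: str) -> "ObjectRef":
        otype, _, oid = text.partition(":")
        if otype not in OTYPES or not oid.isdigit():
            raise ValueError(f"bad object ref: {text!r}")
        return cls(otype, int(oid))


#: SBS standard plate geometries: wells -> (rows, columns).
STANDARD_PLATE_FORMATS = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}


def plate_geometry(format: int) -> tuple[int, int]:
    try:
        return STANDARD_PLATE_FORMATS[int(format)]
    except (KeyError, ValueError, TypeError):
        raise PlateFormatError(
            f"unsupported plate format {format!r}; expected one of "
            f"{sorted(STANDARD_PLATE_FORMATS)}"
        ) from None


def well_address(row_index: int, column_index: int, rows: int | None = None,
                 columns: int | None = None) -> str:
    """0-based grid indices -> bench label, e.g. ``(0, 0) -> "A1"``.

    Rows beyond 'Z' use double letters in bijective base-26 (row 26 -> "AA").
    When *rows*/*columns* are given, out-of-bounds indices raise.
    """
    if row_index < 0 or column_index < 0:
        raise BoundsError(f"negative well indices ({row_index}, {column_index})")
    if rows is not None and row_index >= rows:
        raise BoundsError(f"row {row_index} outside plate with {rows} rows")
    if columns is not None and column_index >= columns:
        raise BoundsError(f"column {column_index} outside plate with {columns} columns")
    letters = ""
    r = row_index + 1  # bijective base-26
    while r > 0:
        r, rem = divmod(r - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return f"{letters}{column_index + 1}"


_ADDRESS_RE = re.compile(r"^\s*([A-Za-z]+)\s*0*(\d+)\s*$")


def parse_address(label: str) -> tuple[int, int]:
    """Bench label -> 0-based (row, column); tolerant of case and zero padding.

    ``"H12"``, ``"h12"`` and ``"H012"`` all give ``(7, 11)``.
    """
    m = _ADDRESS_RE.match(label or "")
    if not m:
        raise BoundsError(f"unparseable well address: {label!r}")
    letters, digits = m.group(1).upper(), m.group(2)
    row = 0
    for ch in letters:
        row = row * 26 + (ord(ch) - ord("A") + 1)
    column = int(digits)
    if column < 1:
        raise BoundsError(f"column number must be >= 1 in {label!r}")
    return row - 1, column - 1


@dataclass
class Screen:
    name: str = ""
    description: str = ""
    plate_refs: list[ObjectRef] = dc_field(default_factory=list)
    reagent_refs: list[ObjectRef] = dc_field(default_factory=list)


@dataclass
class Plate:
    name: str = ""
    rows: int = 8
    columns: int = 12
    # (row_index, column_index) -> well ref; at most one well per position
    well_refs: dict[tuple[int, int], ObjectRef] = dc_field(default_factory=dict)


@dataclass
class Well:
    row_index: int = 0
    column_index: int = 0
    reagent_ref: Optional[ObjectRef] = None
    field_refs: list[ObjectRef] = dc_field(default_factory=list)


@dataclass
class Field:
    index: int = 0
    image_ref: Optional[ObjectRef] = None


@dataclass
class Image:
    """A 5D image (x, y, z, channel, time) referencing external pixel bytes.

    ``pixel_source``, when present, is a path (plus optional plane offset)
    into the original acquisition file; the bytes themselves stay outside
    the store.
    """

    name: str = ""
    size_x: int = 1
    size_y: int = 1
    size_z: int = 1
    size_c: int = 1
    size_t: int = 1
    channel_refs: list[ObjectRef] = dc_field(default_factory=list)
    pixel_source: Optional[dict] = None  # {"path": str, "plane_offset": int}
    acquisition: dict = dc_field(default_factory=dict)


@dataclass
class Channel:
    index: int = 0
    name: str = ""
    emission: Optional[dict] = None  # serialised length Quantity {"value","unit"}


@dataclass
class Reagent:
    identifier: str = ""
    description: str = ""


SHAPE_KINDS = ("rectangle", "ellipse", "polygon", "mask")


@dataclass
class ROI:
    """A region delineating one object (typically a cell) in an image.

    Coordinates are 0-based pixel units, x right / y down; rectangle and
    ellipse geometry is a half-open bounding box ``[x0, y0, x1, y1)``;
    polygons are vertex lists; masks carry a bounding box plus a row-major
    boolean payload whose size matches the box.
    """

    image_ref: Optional[ObjectRef] = None
    shape_kind: str = "rectangle"
    geometry: list = dc_field(default_factory=list)
    z: Optional[int] = None
    c: Optional[int] = None
    t: Optional[int] = None
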