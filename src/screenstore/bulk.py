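"""Bulk annotation: spreadsheet metadata -> map annotations.

Screen metadata usually arrives as one CSV/TSV sheet per plate, one row per
well, keyed by the bench well address ("A1", "b07", ...).  ``load_sheet``
turns each data row into one :class:`MapAnnotation` on the matched well (or
image, when keyed by image name), with pairs ordered exactly as the sheet
columns.  A header like ``Temperature [°C]`` splits into the key
``Temperature`` and the unit ``°C`` stored in the pair's unit slot.

``export_sheet`` is the inverse; a load → export → load round trip
recreates value-identical annotations.

Dialect rules: comma for ``.csv``, tab for ``.tsv``/``.txt`` (overridable),
UTF-8 with BOM tolerance, CRLF and LF both accepted, RFC-4180 quoting.
Well-address matching is case-insensitive and zero-padding-tolerant.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .annotations import BULK_NAMESPACE, MapAnnotation
from .errors import (
    BoundsError,
    SheetMappingError,
    SheetMatchError,
    SheetParseError,
)
from .model import Image, ObjectRef, parse_address, well_address
from .permissions import Principal
from .store import Store

_UNIT_HEADER_RE = re.compile(r"^(.*?)\s*\[([^\[\]]+)\]\s*$")


@dataclass
class SheetMapping:
    """How a sheet maps onto a plate's wells or images."""

    target_level: str = "well"  # "well" (address-keyed) or "image" (name-keyed)
    key_column: str = "Well"
    unit_syntax: bool = True  # parse "Header [unit]" headers
    namespace: str = BULK_NAMESPACE
    on_unmatched: str = "error"  # or "skip"
    delimiter: Optional[str] = None  # default inferred from extension
    validate_units: bool = False  # check header units against the registry


@dataclass
class LoadReport:
    rows_read: int = 0
    annotations_created: int = 0
    unmatched: list[str] = field(default_factory=list)


def _sheet_delimiter(path: Path, override: Optional[str]) -> str:
    if override:
        return override
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def _split_header(header: str, unit_syntax: bool) -> tuple[str, Optional[str]]:
    if unit_syntax:
        m = _UNIT_HEADER_RE.match(header)
        if m:
            return m.group(1), m.group(2)
    return header, None


def _read_sheet(path: Path, delimiter: str) -> tuple[list[str], list[list[str]]]:
    try:
        with open(path, "r", encoding="utf-8-sig", newline="") as fh:
            rows = list(csv.reader(fh, delimiter=delimiter))
    except (OSError, UnicodeDecodeError, csv.Error) as e:
        raise SheetParseError(f"cannot read sheet {path}: {e}") from e
    if not rows:
        raise SheetParseError(f"{path} has no header row")
    header, data = rows[0], rows[1:]
    for i, row in enumerate(data, start=2):
        if len(row) != len(header):
            raise SheetParseError(
                f"{path}:{i}: row has {len(row)} fields, header has {len(header)}")
    return header, data


def _image_names(store: Store, plate: ObjectRef) -> dict[str, list[ObjectRef]]:
    names: dict[str, list[ObjectRef]] = {}
    p = store.get(plate)
    for wref in p.well_refs.values():
        w = store.get(wref)
        for fref in w.field_refs:
            f = store.get(fref)
            if f.image_ref:
                img: Image = store.get(f.image_ref)
                names.setdefault(img.name, []).append(f.image_ref)
    return names


def load_sheet(store: Store, path: str | Path, plate: ObjectRef,
               mapping: SheetMapping | None = None,
               as_user: Optional[Principal] = None) -> LoadReport:
    """Import one sheet onto *plate*; returns a row/annotation/unmatched report."""
    mapping = mapping or SheetMapping()
    path = Path(path)
    store._require(plate)
    header, data = _read_sheet(path, _sheet_delimiter(path, mapping.delimiter))
    try:
        key_idx = header.index(mapping.key_column)
    except ValueError:
        raise SheetMappingError(
            f"key column {mapping.key_column!r} not in header {header}") from None
    pair_headers = [(i, *_split_header(h, mapping.unit_syntax))
                    for i, h in enumerate(header) if i != key_idx]

    plate_obj = store.get(plate)
    image_index = (_image_names(store, plate)
                   if mapping.target_level == "image" else None)

    report = LoadReport()
    for row in data:
        report.rows_read += 1
        key = row[key_idx]
        target = _match_target(plate_obj, image_index, key, mapping)
        if target is None:
            report.unmatched.append(key)
            continue
        ann = MapAnnotation(
            namespace=mapping.namespace,
            pairs=[(h, row[i], unit) for i, h, unit in pair_headers])
        store.annotate(target, ann, as_user=as_user,
                       allow_free_units=not mapping.validate_units)
        report.annotations_created += 1
    return report


def _match_target(plate_obj, image_index, key: str,
                  mapping: SheetMapping) -> Optional[ObjectRef]:
    if mapping.target_level == "image":
        refs = (image_index or {}).get(key, [])
        if len(refs) == 1:
            return refs[0]
        if len(refs) > 1:
            raise SheetMatchError(f"image name {key!r} is ambiguous ({len(refs)} matches)")
        target = None
    else:
        try:
            target = plate_obj.well_refs.get(parse_address(key))
        except BoundsError:
            target = None
    if target is None and mapping.on_unmatched == "error":
        raise SheetMatchError(f"sheet key {key!r} matches nothing on the plate")
    return target


def export_sheet(store: Store, plate: ObjectRef, namespace: str,
                 path: str | Path, target_level: str = "well",
                 delimiter: Optional[str] = None,
                 as_user: Optional[Principal] = None) -> int:
    """Write the plate's map annotations in *namespace* back to a sheet.

    One data row per annotation, wells in row-major order; the header is
    rebuilt from the first annotation's (key, unit) sequence, so a sheet
    previously imported by :func:`load_sheet` round-trips exactly.  Returns
    the number of data rows written.
    """
    path = Path(path)
    delim = _sheet_delimiter(path, delimiter)
    plate_obj = store.get(plate, as_user=as_user)

    if target_level == "image":
        targets = [(name, ref) for name, refs in
                   sorted(_image_names(store, plate).items()) for ref in refs]
        key_header = "Image"
    else:
        targets = [(well_address(r, c), ref)
                   for (r, c), ref in sorted(plate_obj.well_refs.items())]
        key_header = "Well"

    rows_out: list[list[str]] = []
    header_pairs: Optional[list[tuple[str, Optional[str]]]] = None
    for label, ref in targets:
        for _, ann in store.get_annotations(ref, namespace=namespace, as_user=as_user):
            if not isinstance(ann, MapAnnotation):
                continue
            pairs = [(k, u) for k, _, u in ann.pairs]
            if header_pairs is None:
                header_pairs = pairs
            elif pairs != header_pairs:
                raise SheetMappingError(
                    f"annotation on {label} has keys {pairs}, sheet header "
                    f"requires {header_pairs}")
            rows_out.append([label] + [v for _, v, _ in ann.pairs])

    header = [key_header] + [
        (f"{k} [{u}]" if u else k) for k, u in (header_pairs or [])]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(header)
        w.writerows(rows_out)
    return len(rows_out)
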