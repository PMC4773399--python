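"""HDF5-backed columnar feature tables.

Analytic output in HCS — per-cell intensities, areas, shape statistics —
arrives as large tabular arrays: millions of rows, tens of typed columns,
each row linked back to the well/image/ROI it came from.  This module
stores such tables append-only in a single HDF5 file with one resizable
dataset per column, which makes block writes and column-slice reads fast
without a database server.

On-disk layout (consumable by any HDF5 reader):

* group ``/columns`` with one 1-D dataset per column, all equal length;
* root attributes ``table_version``, ``column_names``, ``column_kinds``,
  ``column_widths``, ``column_descriptions``.

Column kinds: ``int64``, ``float64``, ``bool`` (stored as u1 0/1),
``string`` (fixed width, UTF-8, NUL-padded), and the object-reference kinds
``well_ref`` / ``image_ref`` / ``roi_ref`` (stored as int64 object IDs).
Missing values exist only for float64 (NaN); other kinds reject them —
there is no sentinel that round-trips safely for integers or strings.

Querying is deliberately limited: conjunctions of ``column op literal``
terms only, evaluated chunk-wise (no SQL, no joins).  ``backlink`` is the
inverse lookup from a source object to its rows.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import h5py
import numpy as np

from .errors import (
    BoundsError,
    ColumnNameError,
    ColumnTypeError,
    ConditionError,
    SchemaError,
    ShapeError,
    TableCollisionError,
)
from .model import ObjectRef

_VERSION = 1
_CHUNK = 65536

KINDS = ("int64", "float64", "bool", "string", "well_ref", "image_ref", "roi_ref")
REF_KINDS = {"well_ref": "well", "image_ref": "image", "roi_ref": "roi"}
_OPS = ("==", "!=", "<=", ">=", "<", ">")


@dataclass(frozen=True)
class ColumnSpec:
    """One typed column; *width* (bytes of UTF-8) only for string columns."""

    name: str
    kind: str
    description: str = ""
    width: int = 0

    def __post_init__(self):
        if not self.name:
            raise SchemaError("column name must be non-empty")
        if self.kind not in KINDS:
            raise SchemaError(f"unknown column kind {self.kind!r}; expected one of {KINDS}")
        if self.kind == "string" and self.width < 1:
            raise SchemaError(f"string column {self.name!r} needs width >= 1")
        if self.kind != "string" and self.width:
            raise SchemaError(f"width is only valid for string columns ({self.name!r})")


@dataclass(frozen=True)
class TableSchema:
    """Ordered, immutable column list; frozen at table creation."""

    columns: tuple[ColumnSpec, ...]

    def __init__(self, columns: Sequence[ColumnSpec]):
        cols = tuple(columns)
        if not cols:
            raise SchemaError("a table needs at least one column")
        names = [c.name for c in cols]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate column names: {dupes}")
        object.__setattr__(self, "columns", cols)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise ColumnNameError(f"no such column: {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.columns)

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class Condition:
    """AND-conjunction of ``(column, op, literal)`` terms.

    Example: ``Condition([("feature_3", ">", 0.5), ("channel", "==", 1)])``
    or ``Condition.parse("feature_3 > 0.5 AND channel == 1")``.
    """

    terms: tuple[tuple[str, str, object], ...] = field(default_factory=tuple)

    def __init__(self, terms: Sequence[tuple[str, str, object]] = ()):
        object.__setattr__(self, "terms", tuple((c, o, v) for c, o, v in terms))
        for _, op, _ in self.terms:
            if op not in _OPS:
                raise ConditionError(f"unknown operator {op!r}; expected one of {_OPS}")

    _TERM_RE = re.compile(
        r"""^\s*\(?\s*([A-Za-z_][\w.]*)\s*(==|!=|<=|>=|<|>)\s*(.+?)\s*\)?\s*$""")

    @classmethod
    def parse(cls, text: str) -> "Condition":
        terms = []
        for part in re.split(r"\s+(?:AND|and)\s+", text.strip()):
            m = cls._TERM_RE.match(part)
            if not m:
                raise ConditionError(f"cannot parse condition term {part!r}")
            name, op, lit = m.groups()
            terms.append((name, op, _parse_literal(lit)))
        return cls(terms)


def _parse_literal(text: str):
    if len(text) >= 2 and text[0] == text[-1] and text[0] in "'\"":
        return text[1:-1]
    low = text.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        raise ConditionError(f"cannot parse literal {text!r}") from None


def _storage_dtype(spec: ColumnSpec):
    if spec.kind in ("int64", "well_ref", "image_ref", "roi_ref"):
        return np.dtype("<i8")
    if spec.kind == "float64":
        return np.dtype("<f8")
    if spec.kind == "bool":
        return np.dtype("u1")
    return np.dtype(f"S{spec.width}")


def _coerce(spec: ColumnSpec, values) -> np.ndarray:
    """Validate a block's values for one column and return the storage array."""
    kind = spec.kind
    if kind in REF_KINDS:
        want = REF_KINDS[kind]
        if isinstance(values, np.ndarray):
            arr = values
        else:
            vals = []
            for v in values:
                if isinstance(v, ObjectRef):
                    if v.otype != want:
                        raise ColumnTypeError(
                            f"column {spec.name!r} holds {want} refs, got {v.otype}")
                    vals.append(v.oid)
                else:
                    vals.append(v)
            arr = np.asarray(vals)
        if arr.dtype.kind not in "iu":
            raise ColumnTypeError(
                f"column {spec.name!r} ({kind}) needs integer IDs, got {arr.dtype}")
        if arr.size and arr.min() < 0:
            raise ColumnTypeError(f"negative object ID in column {spec.name!r}")
        return arr.astype("<i8")
    if kind == "int64":
        arr = np.asarray(values)
        if arr.dtype.kind == "b" or arr.dtype.kind not in "iu":
            raise ColumnTypeError(
                f"column {spec.name!r} (int64) got dtype {arr.dtype}; "
                "no missing/float values are representable")
        return arr.astype("<i8")
    if kind == "float64":
        arr = np.asarray(values)
        if arr.dtype.kind not in "iuf":
            raise ColumnTypeError(f"column {spec.name!r} (float64) got dtype {arr.dtype}")
        return arr.astype("<f8")
    if kind == "bool":
        arr = np.asarray(values)
        if arr.dtype.kind != "b":
            raise ColumnTypeError(
                f"column {spec.name!r} (bool) got dtype {arr.dtype}; "
                "no missing representation exists for bool")
        return arr.astype("u1")
    # string
    enc = []
    for v in np.asarray(values, dtype=object):
        if not isinstance(v, str):
            raise ColumnTypeError(f"column {spec.name!r} (string) got {type(v).__name__}")
        b = v.encode("utf-8")
        if len(b) > spec.width:
            raise ColumnTypeError(
                f"{v!r} exceeds width {spec.width} of column {spec.name!r}")
        enc.append(b)
    return np.asarray(enc, dtype=f"S{spec.width}")


def _present(spec: ColumnSpec, stored: np.ndarray):
    """Storage array -> user-facing values."""
    if spec.kind == "bool":
        return stored.astype(bool)
    if spec.kind == "string":
        return np.asarray([b.decode("utf-8") for b in stored],
                          dtype=f"U{max(spec.width, 1)}")
    return stored


class FeatureTable:
    """An append-only columnar table in one HDF5 file.

    Use :meth:`create` / :meth:`open`; instances are context managers.
    """

    def __init__(self, h5: h5py.File, schema: TableSchema):
        self._h5 = h5
        self.schema = schema

    # -- lifecycle

    @classmethod
    def create(cls, path: str | Path, schema: TableSchema) -> "FeatureTable":
        """Create an empty table with a frozen schema at *path*."""
        try:
            h5 = h5py.File(path, "x")
        except (FileExistsError, OSError) as e:
            raise TableCollisionError(f"{path} already exists: {e}") from None
        h5.attrs["table_version"] = _VERSION
        h5.attrs["column_names"] = [c.name for c in schema.columns]
        h5.attrs["column_kinds"] = [c.kind for c in schema.columns]
        h5.attrs["column_widths"] = np.asarray([c.width for c in schema.columns],
                                               dtype="<i8")
        h5.attrs["column_descriptions"] = [c.description for c in schema.columns]
        grp = h5.create_group("columns")
        for spec in schema.columns:
            grp.create_dataset(spec.name, shape=(0,), maxshape=(None,),
                               dtype=_storage_dtype(spec), chunks=(_CHUNK,),
                               track_times=False)
        h5.flush()
        return cls(h5, schema)

    @classmethod
    def open(cls, path: str | Path, mode: str = "r+") -> "FeatureTable":
        """Reopen an existing table; the stored schema is reconstructed."""
        if not Path(path).exists():
            raise SchemaError(f"no table at {path}")
        h5 = h5py.File(path, mode)
        try:
            names = [str(n) for n in h5.attrs["column_names"]]
            kinds = [str(k) for k in h5.attrs["column_kinds"]]
            widths = [int(w) for w in h5.attrs["column_widths"]]
            descs = [str(d) for d in h5.attrs["column_descriptions"]]
        except KeyError:
            h5.close()
            raise SchemaError(f"{path} is not a feature table") from None
        schema = TableSchema([ColumnSpec(n, k, d, w)
                              for n, k, w, d in zip(names, kinds, widths, descs)])
        return cls(h5, schema)

    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "FeatureTable":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def path(self) -> str:
        return self._h5.filename

    @property
    def row_count(self) -> int:
        first = self.schema.columns[0].name
        return self._h5["columns"][first].shape[0]

    def _dset(self, name: str) -> h5py.Dataset:
        if name not in self.schema:
            raise ColumnNameError(f"no such column: {name!r}")
        return self._h5["columns"][name]

    # -- writes

    def append_rows(self, block: Mapping[str, Sequence]) -> tuple[int, int]:
        """Append one row block; returns ``(first_row_index, n_rows)``.

        The block must supply every column with equal-length values.  All
        validation happens before any dataset grows, so a rejected block
        leaves the table unchanged.
        """
        names = set(self.schema.names)
        got = set(block)
        if got != names:
            missing, extra = sorted(names - got), sorted(got - names)
            raise ShapeError(f"block mismatch: missing {missing}, unknown {extra}")
        coerced: dict[str, np.ndarray] = {}
        n = None
        for spec in self.schema.columns:
            arr = _coerce(spec, block[spec.name])
            if arr.ndim != 1:
                raise ShapeError(f"column {spec.name!r} block must be 1-D")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ShapeError(
                    f"ragged block: column {spec.name!r} has {arr.shape[0]} "
                    f"values, expected {n}")
            coerced[spec.name] = arr
        start = self.row_count
        for name, arr in coerced.items():
            d = self._h5["columns"][name]
            d.resize((start + n,))
            if n:
                d[start:start + n] = arr
        self._h5.flush()
        return start, int(n)

    # -- reads

    def read(self, columns: Sequence[str] | None = None, start: int = 0,
             stop: int | None = None) -> dict[str, np.ndarray]:
        """Read the half-open row range ``[start, stop)`` for the named columns."""
        stop = self.row_count if stop is None else stop
        if not (0 <= start <= stop <= self.row_count):
            raise BoundsError(
                f"bad range [{start}, {stop}) for table with {self.row_count} rows")
        names = self.schema.names if columns is None else list(columns)
        out = {}
        for name in names:
            spec = self.schema[name]
            out[name] = _present(spec, self._dset(name)[start:stop])
        return out

    def query(self, cond: Condition) -> np.ndarray:
        """Ascending indices of rows satisfying every term of *cond*."""
        self._validate_condition(cond)
        n = self.row_count
        hits = []
        for lo in range(0, n, _CHUNK):
            hi = min(lo + _CHUNK, n)
            mask = np.ones(hi - lo, dtype=bool)
            for name, op, lit in cond.terms:
                spec = self.schema[name]
                col = _present(spec, self._dset(name)[lo:hi])
                lit_v = lit
                if spec.kind == "string":
                    col = np.char.rstrip(col, "\x00") if col.size else col
                mask &= _apply_op(col, op, lit_v)
            hits.append(np.nonzero(mask)[0] + lo)
        if not hits:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(hits).astype(np.int64)

    def _validate_condition(self, cond: Condition) -> None:
        for name, op, lit in cond.terms:
            spec = self.schema[name]  # raises ColumnNameError
            k = spec.kind
            if k in ("int64",) + tuple(REF_KINDS):
                ok = isinstance(lit, (int, np.integer)) and not isinstance(lit, bool)
            elif k == "float64":
                ok = isinstance(lit, (int, float, np.floating, np.integer)) \
                    and not isinstance(lit, bool)
            elif k == "bool":
                ok = isinstance(lit, (bool, np.bool_))
            else:
                ok = isinstance(lit, str)
            if not ok:
                raise ConditionError(
                    f"literal {lit!r} does not match column {name!r} kind {k}")

    def backlink(self, ref_column: str, target: ObjectRef) -> np.ndarray:
        """Rows whose reference column points at *target* (ascending indices)."""
        spec = self.schema[ref_column]
        if spec.kind not in REF_KINDS:
            raise ColumnTypeError(f"{ref_column!r} is not an object-reference column")
        if REF_KINDS[spec.kind] != target.otype:
            raise ColumnTypeError(
                f"{ref_column!r} holds {REF_KINDS[spec.kind]} refs; "
                f"got a {target.otype} ref")
        return self.query(Condition([(ref_column, "==", target.oid)]))

    # -- interop

    def to_csv(self, path: str | Path, start: int = 0, stop: int | None = None,
               columns: Sequence[str] | None = None) -> int:
        """Export a row range as RFC-4180 CSV; returns rows written."""
        data = self.read(columns=columns, start=start, stop=stop)
        names = list(data)
        nrows = len(data[names[0]]) if names else 0
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(names)
            for i in range(nrows):
                w.writerow([_csv_cell(data[n][i]) for n in names])
        return nrows


def _csv_cell(v):
    if isinstance(v, (np.bool_, bool)):
        return "true" if v else "false"
    if isinstance(v, np.floating):
        return repr(float(v))
    if isinstance(v, np.integer):
        return int(v)
    return v


def _apply_op(col: np.ndarray, op: str, lit) -> np.ndarray:
    if op == "==":
        return col == lit
    if op == "!=":
        return col != lit
    if op == "<":
        return col < lit
    if op == "<=":
        return col <= lit
    if op == ">":
        return col > lit
    return col >= lit


def example_wide_schema(n_channels: int = 3, n_features: int = 25) -> TableSchema:
    """Wide layout: one row per ROI, one float column per feature × channel,
    plus the three backlink columns (well, image, ROI)."""
    cols = [ColumnSpec("well", "well_ref", "source well"),
            ColumnSpec("image", "image_ref", "source image"),
            ColumnSpec("roi", "roi_ref", "source ROI (one cell)")]
    for c in range(n_channels):
        for f in range(n_features):
            cols.append(ColumnSpec(f"ch{c}_f{f}", "float64",
                                   f"feature {f} on channel {c}"))
    return TableSchema(cols)


def example_long_schema() -> TableSchema:
    """Long layout: one row per (ROI, channel, feature) measurement."""
    return TableSchema([
        ColumnSpec("well", "well_ref", "source well"),
        ColumnSpec("image", "image_ref", "source image"),
        ColumnSpec("roi", "roi_ref", "source ROI (one cell)"),
        ColumnSpec("channel", "int64", "channel index"),
        ColumnSpec("feature", "int64", "feature index"),
        ColumnSpec("value", "float64", "measured feature value"),
    ])
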