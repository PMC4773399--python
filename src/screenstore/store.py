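"""Single-file object store for HCS metadata.

The store is an embedded relational database (sqlite) addressed by a file
path.  It holds the typed containment hierarchy, ownership records, group
policies, annotations and their links, and registrations of HDF5 feature
tables.  Two sidecar locations live beside the store file:

* ``<path>.files/`` — content-addressed payloads of file annotations;
* ``<path>.index.json`` — the persisted search index (see ``search_index``).

Pixel bytes are never copied in: an :class:`~screenstore.model.Image` keeps
``pixel_source`` as a verbatim path into the original acquisition file.

Object IDs are assigned from per-type monotonic counters and are never
reused within a store's lifetime, so a dangling reference is always
detectable.  Deletion is restricted: removing an object that other objects
still reference raises unless ``cascade=True``, in which case the inbound
references are detached (and referrers that cannot exist without the
target, such as a field whose image is deleted, are removed recursively).

Every read surface takes an optional ``as_user`` principal and enforces the
group-permission rules from :mod:`screenstore.permissions`; ``None`` means
the store's default administrative principal.
"""

from __future__ import annotations

import hashlib
import json
import mimetypes
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from . import model
from .annotations import FileAnnotation, MapAnnotation, TagAnnotation, Annotation
from .errors import (
    AccessError,
    AnnotationError,
    DanglingRefError,
    DeleteRestrictedError,
    DomainHierarchyError,
    PolicyError,
)
from .model import (
    ROI,
    Channel,
    Field,
    Image,
    ObjectRef,
    Plate,
    Reagent,
    Screen,
    Well,
    plate_geometry,
)
from .permissions import (
    ADMIN,
    LEVEL_ORDER,
    Ownership,
    Principal,
    can_annotate as _can_annotate,
    can_read as _can_read,
    check_level,
)
from .quantities import UnitRegistry, DEFAULT_REGISTRY

_SCHEMA = """
CREATE TABLE IF NOT EXISTS id_counters (otype TEXT PRIMARY KEY, next_id INTEGER NOT NULL);
CREATE TABLE IF NOT EXISTS objects (
    otype TEXT NOT NULL, oid INTEGER NOT NULL, payload TEXT NOT NULL,
    PRIMARY KEY (otype, oid));
CREATE TABLE IF NOT EXISTS links (
    src_otype TEXT NOT NULL, src_oid INTEGER NOT NULL,
    dst_otype TEXT NOT NULL, dst_oid INTEGER NOT NULL);
CREATE INDEX IF NOT EXISTS links_dst ON links (dst_otype, dst_oid);
CREATE INDEX IF NOT EXISTS links_src ON links (src_otype, src_oid);
CREATE TABLE IF NOT EXISTS ownership (
    otype TEXT NOT NULL, oid INTEGER NOT NULL,
    owner TEXT NOT NULL, group_id TEXT NOT NULL,
    PRIMARY KEY (otype, oid));
CREATE TABLE IF NOT EXISTS group_policies (group_id TEXT PRIMARY KEY, level TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS ann_links (
    link_id INTEGER PRIMARY KEY AUTOINCREMENT,
    ann_oid INTEGER NOT NULL,
    target_otype TEXT NOT NULL, target_oid INTEGER NOT NULL,
    creator TEXT NOT NULL,
    UNIQUE (ann_oid, target_otype, target_oid));
"""

#: Containment edges of the hierarchy (type level).
CONTAINMENT = {
    "screen": ("plate",),
    "plate": ("well",),
    "well": ("field",),
    "field": ("image",),
    "image": ("channel",),
}


def _reachable_types(root: str) -> set[str]:
    out: set[str] = set()
    frontier = [root]
    while frontier:
        t = frontier.pop()
        for child in CONTAINMENT.get(t, ()):
            if child not in out:
                out.add(child)
                frontier.append(child)
    return out


# ---------------------------------------------------------------------------
# serialisation


def _encode(obj) -> str:
    if isinstance(obj, Screen):
        d = {"name": obj.name, "description": obj.description,
             "plate_refs": [r.oid for r in obj.plate_refs],
             "reagent_refs": [r.oid for r in obj.reagent_refs]}
    elif isinstance(obj, Plate):
        d = {"name": obj.name, "rows": obj.rows, "columns": obj.columns,
             "well_refs": [[r, c, ref.oid] for (r, c), ref in sorted(obj.well_refs.items())]}
    elif isinstance(obj, Well):
        d = {"row_index": obj.row_index, "column_index": obj.column_index,
             "reagent_ref": obj.reagent_ref.oid if obj.reagent_ref else None,
             "field_refs": [r.oid for r in obj.field_refs]}
    elif isinstance(obj, Field):
        d = {"index": obj.index, "image_ref": obj.image_ref.oid if obj.image_ref else None}
    elif isinstance(obj, Image):
        d = {"name": obj.name, "size_x": obj.size_x, "size_y": obj.size_y,
             "size_z": obj.size_z, "size_c": obj.size_c, "size_t": obj.size_t,
             "channel_refs": [r.oid for r in obj.channel_refs],
             "pixel_source": obj.pixel_source, "acquisition": obj.acquisition}
    elif isinstance(obj, Channel):
        d = {"index": obj.index, "name": obj.name, "emission": obj.emission}
    elif isinstance(obj, Reagent):
        d = {"identifier": obj.identifier, "description": obj.description}
    elif isinstance(obj, ROI):
        d = {"image_ref": obj.image_ref.oid if obj.image_ref else None,
             "shape_kind": obj.shape_kind, "geometry": obj.geometry,
             "z": obj.z, "c": obj.c, "t": obj.t}
    elif isinstance(obj, MapAnnotation):
        d = {"kind": "map", "namespace": obj.namespace,
             "pairs": [[k, v, u] for (k, v, u) in obj.pairs], "owner": obj.owner}
    elif isinstance(obj, FileAnnotation):
        d = {"kind": "file", "namespace": obj.namespace, "filename": obj.filename,
             "mimetype": obj.mimetype, "checksum": obj.checksum, "size": obj.size,
             "owner": obj.owner}
    elif isinstance(obj, TagAnnotation):
        d = {"kind": "tag", "text": obj.text, "owner": obj.owner}
    elif isinstance(obj, TableRecord):
        d = {"kind": "table", "path": obj.path, "name": obj.name}
    else:  # pragma: no cover - internal misuse
        raise TypeError(f"unstorable object {type(obj)!r}")
    return json.dumps(d, ensure_ascii=False, separators=(",", ":"))


def _decode(otype: str, payload: str):
    d = json.loads(payload)
    R = ObjectRef
    if otype == "screen":
        return Screen(d["name"], d["description"],
                      [R("plate", i) for i in d["plate_refs"]],
                      [R("reagent", i) for i in d["reagent_refs"]])
    if otype == "plate":
        return Plate(d["name"], d["rows"], d["columns"],
                     {(r, c): R("well", i) for r, c, i in d["well_refs"]})
    if otype == "well":
        return Well(d["row_index"], d["column_index"],
                    R("reagent", d["reagent_ref"]) if d["reagent_ref"] is not None else None,
                    [R("field", i) for i in d["field_refs"]])
    if otype == "field":
        return Field(d["index"],
                     R("image", d["image_ref"]) if d["image_ref"] is not None else None)
    if otype == "image":
        return Image(d["name"], d["size_x"], d["size_y"], d["size_z"], d["size_c"],
                     d["size_t"], [R("channel", i) for i in d["channel_refs"]],
                     d["pixel_source"], d["acquisition"])
    if otype == "channel":
        return Channel(d["index"], d["name"], d["emission"])
    if otype == "reagent":
        return Reagent(d["identifier"], d["description"])
    if otype == "roi":
        return ROI(R("image", d["image_ref"]) if d["image_ref"] is not None else None,
                   d["shape_kind"], d["geometry"], d["z"], d["c"], d["t"])
    if otype == "annotation":
        kind = d["kind"]
        if kind == "map":
            return MapAnnotation(d["namespace"],
                                 [(k, v, u) for k, v, u in d["pairs"]], d["owner"])
        if kind == "file":
            return FileAnnotation(d["namespace"], d["filename"], d["mimetype"],
                                  d["checksum"], d["size"], d["owner"])
        return TagAnnotation(d["text"], d["owner"])
    if otype == "table":
        return TableRecord(d["path"], d.get("name", ""))
    raise DanglingRefError(f"unknown otype {otype!r}")  # pragma: no cover


def _outbound(otype: str, payload: str) -> list[tuple[str, int]]:
    """Reference edges leaving an object, derived from its payload."""
    d = json.loads(payload)
    out: list[tuple[str, int]] = []
    if otype == "screen":
        out += [("plate", i) for i in d["plate_refs"]]
        out += [("reagent", i) for i in d["reagent_refs"]]
    elif otype == "plate":
        out += [("well", i) for _, _, i in d["well_refs"]]
    elif otype == "well":
        if d["reagent_ref"] is not None:
            out.append(("reagent", d["reagent_ref"]))
        out += [("field", i) for i in d["field_refs"]]
    elif otype == "field":
        if d["image_ref"] is not None:
            out.append(("image", d["image_ref"]))
    elif otype == "image":
        out += [("channel", i) for i in d["channel_refs"]]
    elif otype == "roi":
        if d["image_ref"] is not None:
            out.append(("image", d["image_ref"]))
    return out


_CLASS_OTYPE = [
    (Screen, "screen"), (Plate, "plate"), (Well, "well"), (Field, "field"),
    (Image, "image"), (Channel, "channel"), (Reagent, "reagent"), (ROI, "roi"),
]


@dataclass
class TableRecord:
    """Store-side registration of an HDF5 feature table (path + display name)."""

    path: str
    name: str = ""


def _otype_of(obj) -> str:
    if isinstance(obj, (MapAnnotation, FileAnnotation, TagAnnotation)):
        return "annotation"
    if isinstance(obj, TableRecord):
        return "table"
    for cls, otype in _CLASS_OTYPE:
        if isinstance(obj, cls):
            return otype
    raise TypeError(f"not a storable object: {type(obj)!r}")


class Store:
    """Open (or create) the metadata store at *path*.

    Parameters
    ----------
    path:
        Store file location; sidecars are created beside it.
    default_owner, default_group:
        Ownership stamped on objects when the creating call names none.
    registry:
        Unit registry used to validate map-annotation units.
    """

    def __init__(self, path: str | Path, default_owner: str = "admin",
                 default_group: str = "default",
                 registry: UnitRegistry | None = None):
        self.path = Path(path)
        self.default_owner = default_owner
        self.default_group = default_group
        self.registry = registry or DEFAULT_REGISTRY
        self._db = sqlite3.connect(str(self.path))
        # desk-scale single-writer store: trade durability-on-crash for speed
        self._db.execute("PRAGMA synchronous=OFF")
        self._db.execute("PRAGMA journal_mode=MEMORY")
        self._db.executescript(_SCHEMA)
        self._db.commit()

    # -- lifecycle ----------------------------------------------------------

    def close(self) -> None:
        self._db.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def files_dir(self) -> Path:
        return self.path.with_name(self.path.name + ".files")

    @property
    def index_path(self) -> Path:
        return self.path.with_name(self.path.name + ".index.json")

    def _principal(self, as_user: Optional[Principal]) -> Principal:
        return ADMIN if as_user is None else as_user

    # -- IDs and raw object CRUD -------------------------------------------

    def _next_ids(self, otype: str, n: int) -> range:
        cur = self._db.execute(
            "SELECT next_id FROM id_counters WHERE otype=?", (otype,)).fetchone()
        start = cur[0] if cur else 0
        self._db.execute(
            "INSERT INTO id_counters(otype, next_id) VALUES(?,?) "
            "ON CONFLICT(otype) DO UPDATE SET next_id=?",
            (otype, start + n, start + n))
        return range(start, start + n)

    def exists(self, ref: ObjectRef) -> bool:
        row = self._db.execute(
            "SELECT 1 FROM objects WHERE otype=? AND oid=?", (ref.otype, ref.oid)
        ).fetchone()
        return row is not None

    def _require(self, ref: ObjectRef) -> None:
        if not self.exists(ref):
            raise DanglingRefError(f"no such object: {ref}")

    def add(self, obj, owner: str | None = None, group: str | None = None) -> ObjectRef:
        """Store one object, validating its outbound references."""
        return self.add_many([obj], owner=owner, group=group)[0]

    def add_many(self, objs: Sequence, owner: str | None = None,
                 group: str | None = None) -> list[ObjectRef]:
        """Bulk insert of same-or-mixed-type objects in one transaction."""
        if not objs:
            return []
        owner = owner or self.default_owner
        group = group or self.default_group
        encoded = [(_otype_of(o), _encode(o)) for o in objs]
        # validate all referenced objects exist (deduplicated)
        needed: set[tuple[str, int]] = set()
        edges: list[list[tuple[str, int]]] = []
        for otype, payload in encoded:
            e = _outbound(otype, payload)
            edges.append(e)
            needed.update(e)
        for t, i in needed:
            self._require(ObjectRef(t, i))
        refs: list[ObjectRef] = []
        by_type: dict[str, list[int]] = {}
        for otype, _ in encoded:
            by_type.setdefault(otype, []).append(0)
        id_iters = {t: iter(self._next_ids(t, len(v))) for t, v in by_type.items()}
        obj_rows, own_rows, link_rows = [], [], []
        for (otype, payload), e in zip(encoded, edges):
            oid = next(id_iters[otype])
            refs.append(ObjectRef(otype, oid))
            obj_rows.append((otype, oid, payload))
            own_rows.append((otype, oid, owner, group))
            link_rows += [(otype, oid, dt, di) for dt, di in e]
        self._db.executemany("INSERT INTO objects VALUES(?,?,?)", obj_rows)
        self._db.executemany("INSERT INTO ownership VALUES(?,?,?,?)", own_rows)
        if link_rows:
            self._db.executemany("INSERT INTO links VALUES(?,?,?,?)", link_rows)
        self._db.commit()
        return refs

    def get(self, ref: ObjectRef, as_user: Optional[Principal] = None):
        """Fetch and decode an object; checks the caller's read permission."""
        row = self._db.execute(
            "SELECT payload FROM objects WHERE otype=? AND oid=?",
            (ref.otype, ref.oid)).fetchone()
        if row is None:
            raise DanglingRefError(f"no such object: {ref}")
        if not self.can_read(ref, self._principal(as_user)):
            raise AccessError(f"{ref} is not readable by this principal")
        return _decode(ref.otype, row[0])

    def update(self, ref: ObjectRef, obj) -> None:
        """Rewrite an object's payload and its outbound link rows."""
        self._require(ref)
        payload = _encode(obj)
        for t, i in _outbound(ref.otype, payload):
            self._require(ObjectRef(t, i))
        self._db.execute(
            "UPDATE objects SET payload=? WHERE otype=? AND oid=?",
            (payload, ref.otype, ref.oid))
        self._db.execute(
            "DELETE FROM links WHERE src_otype=? AND src_oid=?", (ref.otype, ref.oid))
        self._db.executemany(
            "INSERT INTO links VALUES(?,?,?,?)",
            [(ref.otype, ref.oid, t, i) for t, i in _outbound(ref.otype, payload)])
        self._db.commit()

    def all_refs(self, otype: str | None = None) -> Iterator[ObjectRef]:
        if otype is None:
            rows = self._db.execute("SELECT otype, oid FROM objects ORDER BY otype, oid")
        else:
            rows = self._db.execute(
                "SELECT otype, oid FROM objects WHERE otype=? ORDER BY oid", (otype,))
        for t, i in rows:
            yield ObjectRef(t, i)

    def count(self, otype: str) -> int:
        return self._db.execute(
            "SELECT COUNT(*) FROM objects WHERE otype=?", (otype,)).fetchone()[0]

    # -- deletion -----------------------------------------------------------

    def _inbound(self, ref: ObjectRef) -> list[ObjectRef]:
        rows = self._db.execute(
            "SELECT src_otype, src_oid FROM links WHERE dst_otype=? AND dst_oid=?",
            (ref.otype, ref.oid)).fetchall()
        return [ObjectRef(t, i) for t, i in rows]

    def delete(self, ref: ObjectRef, cascade: bool = False) -> None:
        """Delete an object.

        Without *cascade* the delete fails loudly if anything still
        references the object.  With *cascade*, inbound references are
        detached from their holders; referrers that are meaningless without
        the target (a field or ROI whose image goes away) are deleted
        recursively, and annotation links to the object are dropped.
        """
        self._require(ref)
        inbound = self._inbound(ref)
        ann_linked = self._db.execute(
            "SELECT COUNT(*) FROM ann_links WHERE target_otype=? AND target_oid=?",
            (ref.otype, ref.oid)).fetchone()[0]
        if (inbound or ann_linked) and not cascade:
            raise DeleteRestrictedError(
                f"{ref} still has {len(inbound)} inbound link(s) and "
                f"{ann_linked} annotation link(s); pass cascade=True")
        for src in inbound:
            if not self.exists(src):
                continue
            self._detach(src, ref)
        self._db.execute("DELETE FROM ann_links WHERE target_otype=? AND target_oid=?",
                         (ref.otype, ref.oid))
        if ref.otype == "annotation":
            self._db.execute("DELETE FROM ann_links WHERE ann_oid=?", (ref.oid,))
        self._db.execute("DELETE FROM links WHERE src_otype=? AND src_oid=?",
                         (ref.otype, ref.oid))
        self._db.execute("DELETE FROM objects WHERE otype=? AND oid=?",
                         (ref.otype, ref.oid))
        self._db.execute("DELETE FROM ownership WHERE otype=? AND oid=?",
                         (ref.otype, ref.oid))
        self._db.commit()

    def _detach(self, holder: ObjectRef, target: ObjectRef) -> None:
        obj = self.get(holder)
        if isinstance(obj, Screen):
            obj.plate_refs = [r for r in obj.plate_refs if r != target]
            obj.reagent_refs = [r for r in obj.reagent_refs if r != target]
            self.update(holder, obj)
        elif isinstance(obj, Plate):
            obj.well_refs = {k: v for k, v in obj.well_refs.items() if v != target}
            self.update(holder, obj)
        elif isinstance(obj, Well):
            if obj.reagent_ref == target:
                obj.reagent_ref = None
            obj.field_refs = [r for r in obj.field_refs if r != target]
            self.update(holder, obj)
            # keep field indices contiguous after a field removal
            for i, fref in enumerate(obj.field_refs):
                f = self.get(fref)
                if f.index != i:
                    f.index = i
                    self.update(fref, f)
        elif isinstance(obj, (Field, ROI)):
            # a field/ROI cannot exist without its image
            self.delete(holder, cascade=True)
        elif isinstance(obj, Image):
            obj.channel_refs = [r for r in obj.channel_refs if r != target]
            obj.size_c = len(obj.channel_refs) or 1
            self.update(holder, obj)

    # -- hierarchy builders -------------------------------------------------

    def create_plate(self, name: str, format: int = 96, owner: str | None = None,
                     group: str | None = None) -> ObjectRef:
        """Create a standard-format plate (96 → 8×12, 384 → 16×24, 1536 → 32×48)
        with every well instantiated."""
        rows, columns = plate_geometry(format)
        return self.create_plate_custom(name, rows, columns, owner=owner, group=group)

    def create_plate_custom(self, name: str, rows: int, columns: int,
                            owner: str | None = None,
                            group: str | None = None) -> ObjectRef:
        """Advanced constructor for arbitrary grid geometry."""
        if rows < 1 or columns < 1:
            raise model.PlateFormatError(f"bad plate geometry {rows}×{columns}")
        wells = [Well(r, c) for r in range(rows) for c in range(columns)]
        wrefs = self.add_many(wells, owner=owner, group=group)
        plate = Plate(name, rows, columns,
                      {(w.row_index, w.column_index): ref
                       for w, ref in zip(wells, wrefs)})
        return self.add(plate, owner=owner, group=group)

    def well_at(self, plate: ObjectRef, row_index: int, column_index: int) -> ObjectRef:
        p = self.get(plate)
        try:
            return p.well_refs[(row_index, column_index)]
        except KeyError:
            raise model.BoundsError(
                f"no well at ({row_index},{column_index}) in plate {plate}") from None

    def add_field(self, well: ObjectRef, image: ObjectRef) -> ObjectRef:
        """Append an imaged field to a well; field index continues the sequence."""
        self._require(well)
        self._require(image)
        w = self.get(well)
        fref = self.add(Field(index=len(w.field_refs), image_ref=image))
        w.field_refs.append(fref)
        self.update(well, w)
        return fref

    def count_descendants(self, container: ObjectRef, target_otype: str) -> int:
        """Number of *target_otype* objects reachable via containment."""
        self._require(container)
        if target_otype not in _reachable_types(container.otype):
            raise DomainHierarchyError(
                f"{target_otype!r} is not reachable from a {container.otype!r}")
        count = 0
        frontier = [container]
        while frontier:
            ref = frontier.pop()
            obj = self.get(ref)
            children: list[ObjectRef] = []
            if isinstance(obj, Screen):
                children = list(obj.plate_refs)
            elif isinstance(obj, Plate):
                children = list(obj.well_refs.values())
            elif isinstance(obj, Well):
                children = list(obj.field_refs)
            elif isinstance(obj, Field):
                children = [obj.image_ref] if obj.image_ref else []
            elif isinstance(obj, Image):
                children = list(obj.channel_refs)
            for ch in children:
                if ch.otype == target_otype:
                    count += 1
                if CONTAINMENT.get(ch.otype):
                    frontier.append(ch)
        return count

    # -- ownership and permissions ------------------------------------------

    def ownership(self, ref: ObjectRef) -> Ownership:
        row = self._db.execute(
            "SELECT owner, group_id FROM ownership WHERE otype=? AND oid=?",
            (ref.otype, ref.oid)).fetchone()
        if row is None:
            raise DanglingRefError(f"no ownership record for {ref}")
        return Ownership(row[0], row[1])

    def group_policy(self, group_id: str) -> str:
        row = self._db.execute(
            "SELECT level FROM group_policies WHERE group_id=?", (group_id,)).fetchone()
        return row[0] if row else "private"

    def set_group_policy(self, group_id: str, level: str) -> None:
        """Set a group's permission level.

        Lowering the level while the group already holds objects is refused:
        data visible under the old policy must not silently escape review.
        """
        check_level(level)
        current = self.group_policy(group_id)
        if LEVEL_ORDER[level] < LEVEL_ORDER[current]:
            n = self._db.execute(
                "SELECT COUNT(*) FROM ownership WHERE group_id=?", (group_id,)
            ).fetchone()[0]
            if n:
                raise PolicyError(
                    f"cannot lower group {group_id!r} from {current} to {level}: "
                    f"{n} object(s) exist in the group")
        self._db.execute(
            "INSERT INTO group_policies VALUES(?,?) "
            "ON CONFLICT(group_id) DO UPDATE SET level=?",
            (group_id, level, level))
        self._db.commit()

    def _effective_perm_object(self, ref: ObjectRef) -> ObjectRef:
        """Tables and annotations inherit permissions from a linked target."""
        if ref.otype == "table":
            row = self._db.execute(
                "SELECT dst_otype, dst_oid FROM links "
                "WHERE src_otype='table' AND src_oid=? LIMIT 1", (ref.oid,)).fetchone()
            if row:
                return ObjectRef(row[0], row[1])
        elif ref.otype == "annotation":
            row = self._db.execute(
                "SELECT target_otype, target_oid FROM ann_links WHERE ann_oid=? "
                "ORDER BY link_id LIMIT 1", (ref.oid,)).fetchone()
            if row:
                return ObjectRef(row[0], row[1])
        return ref

    def can_read(self, ref: ObjectRef, p: Optional[Principal] = None) -> bool:
        p = self._principal(p)
        eff = self._effective_perm_object(ref)
        if ref.otype == "table" and eff == ref:
            # an unlinked feature table is owner-private
            own = self.ownership(ref)
            return p.is_admin or p.user_id == own.owner
        own = self.ownership(eff)
        if eff != ref and ref.otype in ("table", "annotation"):
            # inherited case: also allow the artifact's own owner
            if p.user_id == self.ownership(ref).owner:
                return True
        return _can_read(p, own, self.group_policy(own.group))

    def can_annotate(self, ref: ObjectRef, p: Optional[Principal] = None) -> bool:
        p = self._principal(p)
        own = self.ownership(self._effective_perm_object(ref))
        return _can_annotate(p, own, self.group_policy(own.group))

    def reassign_owner(self, ref: ObjectRef, new_owner: str,
                       actor: Optional[Principal] = None) -> Ownership:
        """Transfer ownership (facility-manager-imports-for-scientist workflow).

        Only an admin or the current owner may reassign.  Annotations linked
        to the object keep their original creators.
        """
        actor = self._principal(actor)
        own = self.ownership(ref)
        if not (actor.is_admin or actor.user_id == own.owner):
            raise AccessError(
                f"{actor.user_id!r} may not reassign {ref} owned by {own.owner!r}")
        self._db.execute(
            "UPDATE ownership SET owner=? WHERE otype=? AND oid=?",
            (new_owner, ref.otype, ref.oid))
        self._db.commit()
        return Ownership(new_owner, own.group)

    # -- annotations ---------------------------------------------------------

    def annotate(self, target: ObjectRef, annotation: Annotation,
                 as_user: Optional[Principal] = None,
                 allow_free_units: bool = False) -> ObjectRef:
        """Attach a map/file/tag annotation to *target* and return its ref."""
        p = self._principal(as_user)
        self._require(target)
        if target.otype == "annotation":
            raise AnnotationError("annotations cannot target other annotations")
        if not self.can_annotate(target, p):
            raise AccessError(f"{p.user_id!r} may not annotate {target}")
        annotation.validate()
        if isinstance(annotation, MapAnnotation) and not allow_free_units:
            for k, v, u in annotation.pairs:
                if u is not None and u not in self.registry:
                    raise AnnotationError(
                        f"unit {u!r} on key {k!r} is not in the registry "
                        f"(pass allow_free_units=True to store it anyway)")
        if not annotation.owner:
            annotation.owner = p.user_id
        own = self.ownership(target)
        ref = self.add(annotation, owner=annotation.owner, group=own.group)
        self.link_annotation(ref, target, creator=p.user_id)
        return ref

    def link_annotation(self, ann: ObjectRef, target: ObjectRef,
                        creator: str | None = None) -> None:
        self._require(ann)
        self._require(target)
        try:
            self._db.execute(
                "INSERT INTO ann_links(ann_oid, target_otype, target_oid, creator) "
                "VALUES(?,?,?,?)",
                (ann.oid, target.otype, target.oid, creator or self.default_owner))
        except sqlite3.IntegrityError:
            raise AnnotationError(f"{ann} is already linked to {target}") from None
        self._db.commit()

    def get_annotations(self, target: ObjectRef, namespace: str | None = None,
                        as_user: Optional[Principal] = None
                        ) -> list[tuple[ObjectRef, Annotation]]:
        """Annotations linked to *target*, in link-creation order.

        *namespace* filters by exact match.  The caller must be able to read
        the target.
        """
        p = self._principal(as_user)
        self._require(target)
        if not self.can_read(target, p):
            raise AccessError(f"{target} is not readable by {p.user_id!r}")
        rows = self._db.execute(
            "SELECT ann_oid FROM ann_links WHERE target_otype=? AND target_oid=? "
            "ORDER BY link_id", (target.otype, target.oid)).fetchall()
        out = []
        for (oid,) in rows:
            ref = ObjectRef("annotation", oid)
            ann = self.get(ref)
            ns = getattr(ann, "namespace", None)
            if namespace is not None and ns != namespace:
                continue
            out.append((ref, ann))
        return out

    def query_map(self, key: str, value: str | None = None,
                  as_user: Optional[Principal] = None
                  ) -> list[tuple[ObjectRef, ObjectRef]]:
        """All (target, annotation) links whose map annotation holds *key*
        (and *value*, when given), exact and case-sensitive, ordered by
        (target otype, oid, annotation oid).  Targets the caller cannot read
        are silently excluded."""
        p = self._principal(as_user)
        rows = self._db.execute(
            "SELECT a.ann_oid, a.target_otype, a.target_oid FROM ann_links a "
            "JOIN objects o ON o.otype='annotation' AND o.oid=a.ann_oid").fetchall()
        hits = []
        cache: dict[int, bool] = {}
        for ann_oid, t_otype, t_oid in rows:
            if ann_oid not in cache:
                ann = self.get(ObjectRef("annotation", ann_oid))
                cache[ann_oid] = isinstance(ann, MapAnnotation) and any(
                    k == key and (value is None or v == value)
                    for k, v, _ in ann.pairs)
            if not cache[ann_oid]:
                continue
            target = ObjectRef(t_otype, t_oid)
            if not self.can_read(target, p):
                continue
            hits.append((target, ObjectRef("annotation", ann_oid)))
        hits.sort(key=lambda tr: (tr[0].otype, tr[0].oid, tr[1].oid))
        return hits

    def attach_file(self, target: ObjectRef, path: str | Path, namespace: str = "",
                    mimetype: str | None = None,
                    as_user: Optional[Principal] = None) -> ObjectRef:
        """Copy a file's bytes into the managed area and link a FileAnnotation."""
        path = Path(path)
        try:
            payload = path.read_bytes()
        except OSError as e:
            raise AnnotationError(f"cannot read {path}: {e}") from e
        if mimetype is None:
            mimetype = mimetypes.guess_type(path.name)[0] or "application/octet-stream"
        return self.attach_bytes(target, payload, path.name, namespace, mimetype,
                                 as_user=as_user)

    def attach_bytes(self, target: ObjectRef, payload: bytes, filename: str,
                     namespace: str = "", mimetype: str = "application/octet-stream",
                     as_user: Optional[Principal] = None) -> ObjectRef:
        digest = hashlib.sha256(payload).hexdigest()
        dest = self.files_dir / digest[:2] / digest
        if not dest.exists():
            dest.parent.mkdir(parents=True, exist_ok=True)
            dest.write_bytes(payload)
        ann = FileAnnotation(namespace=namespace, filename=filename,
                             mimetype=mimetype, checksum=digest, size=len(payload))
        return self.annotate(target, ann, as_user=as_user)

    def file_payload(self, ann_ref: ObjectRef,
                     as_user: Optional[Principal] = None) -> bytes:
        ann = self.get(ann_ref, as_user=as_user)
        if not isinstance(ann, FileAnnotation):
            raise AnnotationError(f"{ann_ref} is not a file annotation")
        data = (self.files_dir / ann.checksum[:2] / ann.checksum).read_bytes()
        if hashlib.sha256(data).hexdigest() != ann.checksum:  # pragma: no cover
            raise AnnotationError(f"payload checksum mismatch for {ann_ref}")
        return data

    # -- feature-table registration -----------------------------------------

    def register_table(self, path: str | Path, name: str = "",
                       owner: str | None = None, group: str | None = None,
                       link_to: ObjectRef | None = None) -> ObjectRef:
        """Record an HDF5 feature table in the store; optionally link it to
        the object whose analysis produced it (permissions then follow that
        object; an unlinked table is owner-private)."""
        ref = self.add(TableRecord(str(path), name), owner=owner, group=group)
        if link_to is not None:
            self.link_table(ref, link_to)
        return ref

    def link_table(self, table_ref: ObjectRef, target: ObjectRef) -> None:
        self._require(table_ref)
        self._require(target)
        self._db.execute("INSERT INTO links VALUES(?,?,?,?)",
                         (table_ref.otype, table_ref.oid, target.otype, target.oid))
        self._db.commit()

    def open_table(self, table_ref: ObjectRef, as_user: Optional[Principal] = None):
        """Open a registered feature table for reading, permission-checked."""
        from .tables import FeatureTable
        rec = self.get(table_ref, as_user=as_user)
        return FeatureTable.open(rec.path)
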