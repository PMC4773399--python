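"""Flexible metadata attachments.

Three annotation kinds, all linkable to any stored object (many-to-many):

* :class:`MapAnnotation` — an ordered list of ``(key, value, unit)`` pairs
  under a namespace.  Duplicate keys are allowed and insertion order is
  preserved exactly: the underlying concept is an ordered multimap, and
  experimental protocols genuinely repeat keys ("Wash", "Wash", ...).
  The optional third element is a unit symbol, so a triple like
  ``("Temperature", "37", "°C")`` stores the unit as data rather than
  mangling it into the value.
* :class:`FileAnnotation` — an arbitrary file (analysis script, result
  spreadsheet, PDF) stored by content with a SHA-256 checksum, under a
  namespace so tools can find their own attachments.
* :class:`TagAnnotation` — a bare text label.

Ontology references are a key convention, not a type: a pair
``("Ontology Name", ...)`` next to ``("Ontology ID", ...)`` carries enough
to look the term up elsewhere.

Storage and queries live on :class:`screenstore.store.Store`
(``annotate``, ``get_annotations``, ``query_map``, ``attach_file``); the
wrappers here exist so the annotation layer is usable as a module surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .errors import AnnotationError

#: Namespace stamped on bulk-imported map annotations.
BULK_NAMESPACE = "artifact:/bulk_annotations"


@dataclass
class MapAnnotation:
    namespace: str = ""
    pairs: list[tuple[str, str, Optional[str]]] = field(default_factory=list)
    owner: str = ""

    def validate(self) -> None:
        for entry in self.pairs:
            if len(entry) != 3:
                raise AnnotationError(f"map pair must be (key, value, unit): {entry!r}")
            k, v, u = entry
            if not k:
                raise AnnotationError("map annotation keys must be non-empty")
            if not isinstance(k, str) or not isinstance(v, str):
                raise AnnotationError(f"map keys/values must be text: {entry!r}")

    def values_for(self, key: str) -> list[str]:
        return [v for k, v, _ in self.pairs if k == key]


@dataclass
class FileAnnotation:
    namespace: str = ""
    filename: str = ""
    mimetype: str = "application/octet-stream"
    checksum: str = ""  # sha256 hex of the payload
    size: int = 0
    owner: str = ""

    def validate(self) -> None:
        if not self.checksum:
            raise AnnotationError("file annotation requires a payload checksum")


@dataclass
class TagAnnotation:
    text: str = ""
    owner: str = ""

    def validate(self) -> None:
        if not self.text:
            raise AnnotationError("tag label must be non-empty")


Annotation = Union[MapAnnotation, FileAnnotation, TagAnnotation]


# -- thin functional surface over Store ------------------------------------

def annotate(store, target, annotation, **kw):
    return store.annotate(target, annotation, **kw)


def get_annotations(store, target, namespace=None, **kw):
    return store.get_annotations(target, namespace=namespace, **kw)


def query_map(store, key, value=None, **kw):
    return store.query_map(key, value=value, **kw)


def attach_file(store, target, path, namespace="", mimetype=None, **kw):
    return store.attach_file(target, path, namespace=namespace, mimetype=mimetype, **kw)
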