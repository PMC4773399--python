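"""Token-based text search over the store.

A deliberately small inverted index playing the role a full-text engine
plays in a production deployment: every visible object becomes one document
holding its name, its tag labels, its map-annotation keys and values, its
file-annotation filenames, and the full text of file annotations with text
mimetypes.  Binary payloads are skipped (and counted).

Tokenization splits on non-alphanumeric characters and lowercases; there is
no stemming and there are no stop words, so results are exactly
reproducible.  A query matches a document only if the document contains
ALL query tokens; ranking is by total query-token frequency, ties broken by
(otype, oid).  Results are filtered by the caller's read permission at
query time.

``reindex`` is a full rebuild (idempotent); the index persists as JSON
beside the store file.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .annotations import FileAnnotation, MapAnnotation, TagAnnotation
from .errors import SearchQueryError
from .model import (
    Channel,
    Image,
    ObjectRef,
    Plate,
    Reagent,
    Screen,
    Well,
    well_address,
)
from .permissions import Principal

_TOKEN_RE = re.compile(r"[0-9a-z]+")
_TEXT_EXTENSIONS = (".csv", ".tsv", ".m", ".txt")


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def _is_text_payload(ann: FileAnnotation) -> bool:
    if ann.mimetype.startswith("text/"):
        return True
    return ann.filename.lower().endswith(_TEXT_EXTENSIONS)


def _object_text(obj) -> str:
    if isinstance(obj, Screen):
        return f"{obj.name} {obj.description}"
    if isinstance(obj, (Plate, Image, Channel)):
        return obj.name
    if isinstance(obj, Well):
        return well_address(obj.row_index, obj.column_index)
    if isinstance(obj, Reagent):
        return f"{obj.identifier} {obj.description}"
    name = getattr(obj, "name", "")
    return name if isinstance(name, str) else ""


@dataclass
class ReindexReport:
    documents: int = 0
    binary_payloads_skipped: int = 0


class SearchIndex:
    """In-memory inverted index with JSON persistence."""

    def __init__(self):
        # (otype, oid) -> token -> frequency
        self._docs: dict[tuple[str, int], Counter] = {}

    # -- building

    def reindex(self, store) -> ReindexReport:
        """Full rebuild from the store's current contents."""
        self._docs.clear()
        report = ReindexReport()
        for ref in store.all_refs():
            if ref.otype == "annotation":
                continue
            obj = store.get(ref)
            parts = [_object_text(obj)]
            for ann_ref, ann in store.get_annotations(ref):
                if isinstance(ann, TagAnnotation):
                    parts.append(ann.text)
                elif isinstance(ann, MapAnnotation):
                    parts.extend(f"{k} {v}" for k, v, _ in ann.pairs)
                elif isinstance(ann, FileAnnotation):
                    parts.append(ann.filename)
                    if _is_text_payload(ann):
                        payload = store.file_payload(ann_ref)
                        parts.append(payload.decode("utf-8", errors="replace"))
                    else:
                        report.binary_payloads_skipped += 1
            tokens = Counter()
            for part in parts:
                tokens.update(tokenize(part))
            self._docs[(ref.otype, ref.oid)] = tokens
            report.documents += 1
        return report

    # -- querying

    def search(self, query: str, store=None,
               caller: Optional[Principal] = None) -> list[tuple[ObjectRef, int]]:
        """Objects whose documents contain every query token.

        Returns ``(ref, score)`` pairs sorted by descending score, ties by
        (otype, oid).  When *store* is given, objects the caller cannot read
        are dropped.
        """
        tokens = tokenize(query)
        if not tokens:
            raise SearchQueryError(f"query {query!r} contains no searchable tokens")
        hits = []
        for (otype, oid), doc in self._docs.items():
            if all(doc.get(t, 0) > 0 for t in tokens):
                ref = ObjectRef(otype, oid)
                if store is not None and not store.can_read(ref, caller):
                    continue
                hits.append((ref, sum(doc[t] for t in tokens)))
        hits.sort(key=lambda h: (-h[1], h[0].otype, h[0].oid))
        return hits

    # -- persistence

    def save(self, path: str | Path) -> None:
        data = {f"{t}:{i}": dict(c) for (t, i), c in self._docs.items()}
        Path(path).write_text(json.dumps(data, ensure_ascii=False), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SearchIndex":
        idx = cls()
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        for key, counts in data.items():
            otype, _, oid = key.rpartition(":")
            idx._docs[(otype, int(oid))] = Counter(counts)
        return idx


def reindex(store) -> ReindexReport:
    """Rebuild the store's persistent index in place."""
    idx = SearchIndex()
    report = idx.reindex(store)
    idx.save(store.index_path)
    return report


def search(store, query: str,
           caller: Optional[Principal] = None) -> list[tuple[ObjectRef, int]]:
    """Search using the store's persisted index (building it if absent)."""
    if store.index_path.exists():
        idx = SearchIndex.load(store.index_path)
    else:
        idx = SearchIndex()
        idx.reindex(store)
        idx.save(store.index_path)
    return idx.search(query, store=store, caller=caller)
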