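# Methods

This note records how `screenstore` models HCS metadata, the conventions
and numerical choices baked into each layer, what the synthetic generator
does and does not emulate, and the design decisions taken where more than
one reasonable contract existed.

## The data model

The containment hierarchy is Screen → Plate → Well → Field → Image →
Channel, with Reagents linked to wells and ROIs linked to images.  A
*field* is one imaged position inside a well and carries exactly one
image; an image is 5-dimensional (x, y, z, channel, time) and may point at
its pixel bytes via `pixel_source`, a verbatim external path that the
store never resolves eagerly or copies — the store manages metadata, not
pixels.

Standard plate formats follow the SBS conventions: 96 → 8×12,
384 → 16×24, 1536 → 32×48.  Arbitrary grids are available through
`create_plate_custom`.  All indices are 0-based internally; user-facing
well labels are bench-style letter + 1-based number (`A1`, rows past `Z`
continue `AA`, `AB`, … in bijective base-26), and parsing is
case-insensitive and zero-padding-tolerant (`a01` ≡ `A1`).

Object IDs are per-type monotonic counters and are never reused, so any
dangling reference is detectable.  Deletion is restricted: removing an
object that is still referenced raises unless `cascade=True`, in which
case inbound references are detached from their holders; holders that are
meaningless without the target (a field or ROI whose image is deleted)
are removed recursively, and well field indices are re-packed to stay
contiguous.  A well belongs to at most one plate.

ROI geometry is 0-based pixel units, x right / y down, with half-open
bounding boxes; masks carry a bounding box plus a row-major boolean
payload of matching size.

Persistence is a single sqlite file.  Because the store is single-writer
and desk-scale, sqlite's `synchronous` and journal settings are relaxed in
favour of bulk-insert speed; a crash mid-transaction can lose the last
transaction but not corrupt committed state semantics relied on by the
API.

## Quantities

Units are single symbols from a registry mapping each symbol to
`(dimension, factor, offset)` with `base = value·factor + offset`;
conversions pass through the per-dimension base unit (m, s, K, V, Pa, Hz,
rad).  Temperature is affine (°C, °F) and applies to absolute
temperatures only — there is no temperature-difference type, which keeps
the conversion contract unambiguous.  Symbols are case-sensitive UTF-8;
bare `C` is rejected to avoid the coulomb ambiguity.  The default
registry covers SI base units plus the units that occur in microscopy
acquisition metadata (nm, µm, mm, ms, µs, min, h, mV, kHz, bar, deg,
°C, °F); chemistry units such as molarity are deliberately not included
by default and can be merged from a plain-text TSV
(`symbol, dimension, factor, offset`) via `UnitRegistry.load_table`.
Round-trip conversions are exact to ≤1e-9 (relative for linear units,
absolute for affine), which the suite property-tests over the whole
registry.

## Annotations

Map annotations are ordered lists of `(key, value, unit)` triples under a
namespace.  Duplicate keys are allowed and insertion order is preserved
exactly: the concept is an ordered multimap and experimental protocols
genuinely repeat keys.  The unit is a distinct third slot rather than a
value suffix; when present it is validated against the unit registry
unless `allow_free_units=True`.  Annotations are shared objects and may
link to many targets (and one target may hold many annotations); the
`(annotation, target)` link is unique.  `query_map` is exact and
case-sensitive by design — fuzzy matching belongs to the search layer, so
the typed-query strategy and the indexed-search strategy stay separable.

File annotations are stored content-addressed (SHA-256) under a managed
directory beside the store file; payloads are immutable and retrieval
re-verifies the checksum.  Mimetypes are inferred from the filename when
not given, falling back to `application/octet-stream`.

Ontology references are a key convention, not a type: a pair
`("Ontology Name", …)` next to `("Ontology ID", …)` carries enough for an
external lookup.  Bulk-imported annotations use the reserved namespace
`artifact:/bulk_annotations`.

## Feature tables

One HDF5 file per table; one resizable 1-D dataset per column under
`/columns`, schema in root attributes — a layout any HDF5 reader can
consume without this package.  Column kinds: `int64`, `float64`, `bool`
(stored as u1), fixed-width UTF-8 `string` (NUL-padded; width is a byte
budget), and object-reference kinds stored as int64 IDs.  The schema is
frozen at creation; the table is append-only (no update or delete), which
both mirrors the provenance role of analytic output and makes atomicity
simple: a block is fully validated before any dataset grows, so a
rejected append leaves the file untouched.

Missing values exist only for `float64` (NaN).  Integer, boolean and
string columns reject them: there is no sentinel that survives a round
trip unambiguously, and silently coercing to one would corrupt backlink
IDs.

Queries are AND-conjunctions of `column op literal` terms with
`op ∈ {==, !=, <, <=, >, >=}` — deliberately far short of SQL.  They are
evaluated chunk-wise (65,536 rows per chunk, a performance detail that
cannot change results).  `backlink(column, ref)` is defined as
`query(column == ref.oid)` after checking that the column's reference
kind matches the target type.

Both canonical layouts of the worked example are supported: *wide* (one
row per ROI, one column per feature × channel; 78 columns for 3 channels
× 25 features: 3 backlinks + 75 features) and *long* (one row per
ROI × channel × feature; 7,200,000 rows at the full example size).  The
two layouts answer different access patterns — wide for per-cell vectors,
long for per-measurement scans — and the generator can produce either.

## Bulk annotation

One sheet row becomes one map annotation on the well (or image) matched
by the key column, with pairs ordered exactly as the sheet columns; a
header `Temperature [°C]` contributes key `Temperature` and unit `°C`.
Delimiter follows the extension (comma for `.csv`, tab for `.tsv`/`.txt`)
with an override; UTF-8 with BOM tolerance; CRLF and LF both accepted;
RFC-4180 quoting.  Unmatched keys either raise or are counted and
skipped, and `annotations_created + unmatched == rows_read` holds in skip
mode.  Export rebuilds the header from the first annotation's (key, unit)
sequence and refuses mixed key sequences in one namespace rather than
writing a ragged sheet; load → export → load therefore preserves the
multiset of (key, value, unit) sequences exactly, which the suite fuzzes.

## Search

The index is a plain inverted index: one document per visible object,
containing its name (wells contribute their bench label), tag labels, map
keys and values, file-annotation filenames, and the decoded contents of
text attachments (`text/*` mimetypes plus `.csv`/`.tsv`/`.m`/`.txt` by
extension); binary payloads are skipped and counted.  Tokenization splits
on non-alphanumerics and lowercases — no stemming, no stop words — so
results are exactly reproducible and a brute-force scan is a usable
oracle.  A document matches only if it contains *all* query tokens;
ranking is total query-token frequency with ties broken by (otype, oid).
Permission filtering happens at query time against the caller, so a stale
index cannot leak objects a caller could never read.  `reindex` is a full
rebuild; incremental indexing is omitted at desk scale.

## Permissions

Each object carries one ownership record (owner, group); each group has
one policy level on the ladder private < group_read < group_read_annotate
< public_read.  Reads: admin, owner, members at ≥ group_read, anyone at
public_read.  Annotation: admin, owner, or members at exactly
group_read_annotate — public visibility never implies write access.
Feature tables and annotations inherit the permissions of the object they
are linked to; an unlinked table is owner-private.  Lowering a group's
level while the group holds objects is refused, so data never silently
escapes a visibility decision.  Every read surface (object fetch,
annotation listing, map queries, table opening, search) consults the same
two rule functions, which the suite exercises against the exhaustive
4-level × {owner, member, non-member} truth table.

## Pixel statistics and thumbnails

`plane_stats` returns exact order statistics; the median of an even-sized
plane is the midpoint of the two central values.  Thumbnails: each active
channel is windowed `w = clamp((v − min)/(max − min), 0, 1)`, scaled to
[0, 255], tinted by its RGB colour, summed with saturation at 255;
downsampling is block-mean over the largest integer factor followed by
nearest-neighbour to the exact target, and final values round half-up.
Rounding and resampling are fixed so that identical settings produce
byte-identical thumbnails, channel order never matters, and shrinking a
window from above brightens in-window pixels monotonically.  TIFF input
is restricted to single-plane grayscale; there is no gamma or lookup
table.

## Synthetic screens

The generator's default configuration *is* the worked example: 1 plate of
384 wells, 5 fields/well, 3 channels, 50 cells/image, 25
features/channel/cell, giving 1,920 images, 96,000 ROIs and 7,200,000
long-format rows.  Cell counts can alternatively be Poisson-distributed;
feature values are per-feature Gaussian (default mean 0, sd 1); cell ROIs
are uniformly placed 16–48 px rectangles inside 1024×1024 images; every
well gets a distinct synthetic compound ID; the companion sheet carries
the reagent plus `Cell line` (U2OS) and `Temperature [°C]` (37) columns.
All randomness flows from a single seeded NumPy PCG64 generator, and HDF5
datasets are written without timestamps, so equal seeds give
byte-identical feature tables.

These are storage-exercising conventions, not biology: real screens have
spatially correlated features, plate and batch effects, segmentation
errors, heterogeneous cell counts and phenotype structure.  Passing tests
demonstrate that the storage, linkage, query, permission and round-trip
machinery is correct at realistic scale — not that any biological signal
is modelled.

Problem sizes used by the test suite: the full worked example runs once
(about ten seconds); everything else uses 96-well screens with 2–5
fields/channels/cells/features, 100-seed random tables of up to 10,000
rows for query-oracle parity, and fuzzed sheets of a few dozen rows —
sizes chosen so the whole suite stays well under a minute while still
crossing every block and chunk boundary.

## Known limitations

No proprietary microscopy formats (single-plane baseline TIFF only), no
client–server protocol or authentication, no SQL or cross-table joins, no
concurrent writers, no Excel input, no compound-unit algebra (µm/s), no
ontology lookups beyond the key convention, and the search layer has no
fuzzy matching, phrases or field scoping.
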