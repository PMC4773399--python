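# screenstore

Desk-scale metadata management for high-content screening (HCS).

An image-based screen produces three very different kinds of data at once:
the **experimental metadata** of the plate itself (screen → plate → well →
field → image → channel, plus the reagent in each well), the **flexible
annotations** a lab layers on top (key-value pairs such as
`"Cell line":"U2OS"` or unit-bearing `"Temperature":"37":"°C"`, attached
files, tags), and the **analytic output** of image analysis — millions of
per-cell feature measurements, each of which must stay linked to the well,
image and cell it came from. `screenstore` stores all three behind one
API, each in the storage strategy that fits it:

* a **typed object store** (single-file sqlite) for the containment
  hierarchy, with stable integer IDs, referential integrity, restricted
  deletes, and in-place references to external pixel files (bytes are never
  copied into the store);
* an **annotation layer**: ordered key-value map annotations with optional
  units validated against a unit registry, content-addressed file
  annotations with SHA-256 checksums, and tags — all linkable many-to-many
  to any object and queryable by exact key/value;
* an **HDF5 columnar feature store**: append-only tables with typed columns
  (including `well_ref`/`image_ref`/`roi_ref` backlink columns), block
  appends, column-slice reads, and a deliberately limited query language
  (AND-conjunctions of `column op literal`);

plus bulk CSV/TSV import of per-well metadata sheets, a token-based search
index across names/tags/annotations/attached text, group-based permissions
(private < group-read < group-read-annotate < public-read), per-plane pixel
statistics with windowed thumbnail rendering, a seeded synthetic-screen
generator, and a `screenstore` command-line tool.

It is aimed at individual labs and method developers who need
OMERO-style metadata discipline at a scale where a client–server
deployment is overkill.

## Worked example

The canonical sizing exercise for an HCS feature store is the analytic
output of a single 384-well plate imaged at 5 fields per well with 3
channels, 50 cells per image, and 25 features per channel per cell.  In
long layout (one row per cell × channel × feature) that is

384 wells × 5 images × 50 cells × 3 channels × 25 features = **7,200,000 rows**,

and in wide layout (one row per cell) it is 96,000 rows × 78 columns
(3 backlink columns + 75 feature columns).

```python
import screenstore as ss

store = ss.Store("screen.db")
config = ss.ScreenConfig(seed=1)          # defaults are the sizes above
summary = ss.generate(config, store, "features.h5", layout="long")
print(summary.wells, summary.images, summary.rois, summary.feature_rows)
# 384 1920 96000 7200000

with ss.FeatureTable.open("features.h5") as t:
    hits = t.query(ss.Condition.parse("value > 0.5 AND channel == 1"))
    roi_rows = t.backlink("roi", ss.ObjectRef("roi", 0))
print(len(roi_rows))
# 75        <- one cell: 3 channels x 25 features

q = ss.convert(ss.quantity(37, "°C"), "K")
print(q.value, q.unit)
# 310.15 K
```

The same flow from the shell:

```sh
screenstore --store screen.db gen --seed 1 --table features.h5
screenstore table-info features.h5          # rows  7200000
screenstore --store screen.db query-map --key "Cell line" --value U2OS
```

Generating and writing the full 7.2-million-row example takes a few
seconds on one CPU.

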