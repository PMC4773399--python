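"""Seeded generator of complete synthetic screens.

Builds everything the rest of the package consumes — the containment
hierarchy, per-well reagents, bulk-annotation sheets, rectangular
single-cell ROIs, optional pixel planes, and long/wide feature tables —
with no external data.  The default configuration is the canonical
worked example of a screening plate's analytic output: one 384-well plate,
5 fields per well, 3 channels, 50 cells per image, 25 features per channel
per cell, which yields 1,920 images, 96,000 ROIs, and 7,200,000 rows in
the long-format feature table (384 × 5 × 50 × 3 × 25).

All randomness comes from one :class:`numpy.random.Generator` (PCG64)
seeded from ``ScreenConfig.seed``, so a given configuration is fully
reproducible: identical seeds give byte-identical feature tables.  The
distributions (Gaussian feature values, optionally Poisson cell counts,
uniformly placed cell boxes) are simulation conventions for exercising the
storage machinery, not a phenotype model.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import ROI, Channel, Field, Image, ObjectRef, Reagent, Screen, well_address
from .store import Store
from .tables import FeatureTable, example_long_schema, example_wide_schema

_APPEND_BLOCK = 600_000  # rows per HDF5 append when writing long tables


@dataclass
class ScreenConfig:
    """Shape and distributions of one synthetic screen.  *seed* is mandatory."""

    seed: int
    n_plates: int = 1
    plate_format: int = 384
    fields_per_well: int = 5
    channels: int = 3
    cells_per_image: float = 50
    cells_distribution: str = "constant"  # "constant" or "poisson" (mean)
    n_features: int = 25
    # per-feature Gaussian (mean, sd); defaults: mean 0, sd 1 for every feature
    feature_means: Optional[Sequence[float]] = None
    feature_sds: Optional[Sequence[float]] = None
    image_size: tuple[int, int] = (1024, 1024)  # (size_x, size_y)
    cell_line: str = "U2OS"
    temperature_c: str = "37"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("ScreenConfig.seed is mandatory")
        for name in ("n_plates", "fields_per_well", "channels", "n_features"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cells_distribution not in ("constant", "poisson"):
            raise ValueError(f"unknown cells_distribution {self.cells_distribution!r}")

    def means_sds(self) -> tuple[np.ndarray, np.ndarray]:
        means = np.asarray(self.feature_means if self.feature_means is not None
                           else np.zeros(self.n_features), dtype=float)
        sds = np.asarray(self.feature_sds if self.feature_sds is not None
                         else np.ones(self.n_features), dtype=float)
        if means.shape != (self.n_features,) or sds.shape != (self.n_features,):
            raise ValueError("feature_means/feature_sds must have n_features entries")
        return means, sds

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "image_size" in data:
            data["image_size"] = tuple(data["image_size"])
        return cls(**data)


@dataclass
class GenerateSummary:
    wells: int = 0
    images: int = 0
    rois: int = 0
    feature_rows: int = 0
    screen_ref: Optional[ObjectRef] = None
    plate_refs: list[ObjectRef] = dc_field(default_factory=list)
    table_ref: Optional[ObjectRef] = None


def reagent_id(plate_idx: int, well_idx: int) -> str:
    return f"CPD-{plate_idx + 1:02d}-{well_idx + 1:04d}"


def generate(config: ScreenConfig, store: Store, table_path: str | Path | None,
             layout: str = "long", owner: str | None = None,
             group: str | None = None) -> GenerateSummary:
    """Populate *store* with a synthetic screen and write its feature table.

    ``layout`` selects the feature-table shape: ``"long"`` (one row per
    ROI × channel × feature), ``"wide"`` (one row per ROI, one column per
    feature × channel), or ``"none"`` to skip the table.  Pixel planes are
    not generated here; use :func:`synthetic_plane` on demand.
    """
    if layout not in ("long", "wide", "none"):
        raise ValueError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(config.seed)
    means, sds = config.means_sds()
    summary = GenerateSummary()

    screen_ref = store.add(Screen(name=f"synthetic-screen-{config.seed}",
                                  description="generated synthetic screen"),
                           owner=owner, group=group)
    summary.screen_ref = screen_ref

    table: Optional[FeatureTable] = None
    if table_path is not None and layout != "none":
        schema = (example_long_schema() if layout == "long"
                  else example_wide_schema(config.channels, config.n_features))
        table = FeatureTable.create(table_path, schema)

    size_x, size_y = config.image_size
    for p in range(config.n_plates):
        plate_ref = store.create_plate(f"Plate-{p + 1}", config.plate_format,
                                       owner=owner, group=group)
        summary.plate_refs.append(plate_ref)
        plate = store.get(plate_ref)
        screen = store.get(screen_ref)
        screen.plate_refs.append(plate_ref)
        well_items = sorted(plate.well_refs.items())
        summary.wells += len(well_items)

        # reagents: one compound per well
        reagents = [Reagent(identifier=reagent_id(p, i),
                            description="synthetic compound")
                    for i in range(len(well_items))]
        reagent_refs = store.add_many(reagents, owner=owner, group=group)
        screen.reagent_refs.extend(reagent_refs)
        store.update(screen_ref, screen)

        # images + channels + fields, batched per plate
        n_images = len(well_items) * config.fields_per_well
        channels = [Channel(index=c, name=f"ch{c}")
                    for _ in range(n_images) for c in range(config.channels)]
        channel_refs = store.add_many(channels, owner=owner, group=group)
        images = []
        img_meta = []
        k = 0
        for (r, c), wref in well_items:
            for f_idx in range(config.fields_per_well):
                crefs = channel_refs[k * config.channels:(k + 1) * config.channels]
                images.append(Image(
                    name=f"P{p + 1}-{well_address(r, c)}-F{f_idx}",
                    size_x=size_x, size_y=size_y, size_z=1,
                    size_c=max(config.channels, 1), size_t=1,
                    channel_refs=list(crefs)))
                img_meta.append((wref, f_idx))
                k += 1
        image_refs = store.add_many(images, owner=owner, group=group)
        fields = [Field(index=f_idx, image_ref=iref)
                  for (wref, f_idx), iref in zip(img_meta, image_refs)]
        field_refs = store.add_many(fields, owner=owner, group=group)
        # attach fields and reagents to wells (one update per well)
        for wi, ((rc), wref) in enumerate(well_items):
            w = store.get(wref)
            w.reagent_ref = reagent_refs[wi]
            w.field_refs = field_refs[wi * config.fields_per_well:
                                      (wi + 1) * config.fields_per_well]
            store.update(wref, w)
        summary.images += len(image_refs)

        # cells: one rectangular ROI per cell, inside image bounds
        if config.cells_distribution == "poisson":
            cells = rng.poisson(config.cells_per_image, size=n_images)
        else:
            cells = np.full(n_images, int(config.cells_per_image), dtype=int)
        total_cells = int(cells.sum())
        box_w = rng.integers(16, 48, size=total_cells)
        box_h = rng.integers(16, 48, size=total_cells)
        x0 = rng.integers(0, np.maximum(size_x - box_w, 1))
        y0 = rng.integers(0, np.maximum(size_y - box_h, 1))
        rois = []
        pos = 0
        for i, iref in enumerate(image_refs):
            for _ in range(cells[i]):
                rois.append(ROI(image_ref=iref, shape_kind="rectangle",
                                geometry=[int(x0[pos]), int(y0[pos]),
                                          int(x0[pos] + box_w[pos]),
                                          int(y0[pos] + box_h[pos])],
                                z=0, t=0))
                pos += 1
        roi_refs = store.add_many(rois, owner=owner, group=group)
        summary.rois += len(roi_refs)

        if table is not None:
            _write_features(table, layout, config, rng, means, sds,
                            well_items, image_refs, roi_refs, cells)

    if table is not None:
        summary.feature_rows = table.row_count
        table.close()
        summary.table_ref = store.register_table(
            str(table_path), name=f"features-{layout}", owner=owner, group=group,
            link_to=screen_ref)
    return summary


def _write_features(table, layout, config, rng, means, sds,
                    well_items, image_refs, roi_refs, cells) -> None:
    n_images = len(image_refs)
    fpw = config.fields_per_well
    nC, nF = config.channels, config.n_features
    # per-ROI backlink oids
    img_oids = np.repeat(np.asarray([r.oid for r in image_refs]), cells)
    well_oids_per_img = np.repeat(
        np.asarray([wref.oid for _, wref in well_items]), fpw)[:n_images]
    well_oids = np.repeat(well_oids_per_img, cells)
    roi_oids = np.asarray([r.oid for r in roi_refs])
    n_rois = roi_oids.size

    if layout == "wide":
        block = {"well": well_oids, "image": img_oids, "roi": roi_oids}
        for c in range(nC):
            for f in range(nF):
                block[f"ch{c}_f{f}"] = means[f] + sds[f] * rng.standard_normal(n_rois)
        table.append_rows(block)
        return

    per_roi = nC * nF
    feat_idx_one = np.tile(np.arange(nF), nC)
    chan_idx_one = np.repeat(np.arange(nC), nF)
    rois_per_block = max(_APPEND_BLOCK // max(per_roi, 1), 1)
    for lo in range(0, n_rois, rois_per_block):
        hi = min(lo + rois_per_block, n_rois)
        m = hi - lo
        feat = np.tile(feat_idx_one, m)
        chan = np.tile(chan_idx_one, m)
        z = rng.standard_normal(m * per_roi)
        values = means[feat] + sds[feat] * z
        table.append_rows({
            "well": np.repeat(well_oids[lo:hi], per_roi),
            "image": np.repeat(img_oids[lo:hi], per_roi),
            "roi": np.repeat(roi_oids[lo:hi], per_roi),
            "channel": chan,
            "feature": feat,
            "value": values,
        })


def generate_sheet(config: ScreenConfig, path: str | Path) -> int:
    """Write a per-well metadata sheet (reagent, cell line, temperature)
    for one plate of the configured format; returns data rows written.

    The sheet is shaped for :func:`screenstore.bulk.load_sheet` with the
    default mapping.
    """
    from .model import plate_geometry

    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    n_wells = 0
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(["Well", "Reagent", "Cell line", "Temperature [°C]"])
        if config.n_plates > 0:
            rows, cols = plate_geometry(config.plate_format)
            for r in range(rows):
                for c in range(cols):
                    idx = r * cols + c
                    w.writerow([well_address(r, c), reagent_id(0, idx),
                                config.cell_line, config.temperature_c])
                    n_wells += 1
    return n_wells


def synthetic_plane(size_y: int, size_x: int, boxes: Sequence[Sequence[int]],
                    rng: np.random.Generator, background: float = 100.0,
                    amplitude: float = 3000.0, noise_sd: float = 20.0) -> np.ndarray:
    """Render one uint16 plane with a Gaussian blob per ROI bounding box.

    Generated only on request — pixel data is deliberately not part of
    :func:`generate` so the large worked example stays metadata-only.
    """
    yy, xx = np.mgrid[0:size_y, 0:size_x]
    img = np.full((size_y, size_x), background, dtype=float)
    img += rng.normal(0.0, noise_sd, size=img.shape)
    for x0, y0, x1, y1 in boxes:
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        sx = max((x1 - x0) / 4.0, 1.0)
        sy = max((y1 - y0) / 4.0, 1.0)
        img += amplitude * np.exp(-(((xx - cx) ** 2) / (2 * sx ** 2)
                                    + ((yy - cy) ** 2) / (2 * sy ** 2)))
    return np.clip(img, 0, 65535).astype(np.uint16)
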