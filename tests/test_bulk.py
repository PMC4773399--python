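"""Bulk CSV/TSV import/export of map annotations."""

import numpy as np
import pytest

import screenstore as ss
from screenstore.bulk import SheetMapping, export_sheet, load_sheet
from screenstore.errors import SheetMappingError, SheetMatchError, SheetParseError


@pytest.fixture
def plate(store):
    return store, store.create_plate("p", 384)


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


def test_load_sheet_worked_example(plate, tmp_path):
    store, pref = plate
    sheet = _write(tmp_path / "m.csv",
                   "Well,Cell line,Temperature [°C]\nA1,U2OS,37\nB1,HeLa,37\n")
    report = load_sheet(store, sheet, pref)
    assert (report.rows_read, report.annotations_created) == (2, 2)
    a1 = store.well_at(pref, 0, 0)
    (_, ann), = store.get_annotations(a1)
    assert ann.pairs == [("Cell line", "U2OS", None), ("Temperature", "37", "°C")]
    assert ann.namespace == ss.BULK_NAMESPACE
    b1 = store.well_at(pref, 1, 0)
    (_, ann_b), = store.get_annotations(b1)
    assert ann_b.pairs[0] == ("Cell line", "HeLa", None)


def test_header_only_sheet(plate, tmp_path):
    store, pref = plate
    sheet = _write(tmp_path / "m.csv", "Well,Cell line\n")
    report = load_sheet(store, sheet, pref)
    assert (report.rows_read, report.annotations_created,
            report.unmatched) == (0, 0, [])


def test_unmatched_key_skip_and_error(plate, tmp_path):
    store, pref = plate
    sheet = _write(tmp_path / "m.csv", "Well,K\nZ99,v\nA1,v\n")
    report = load_sheet(store, sheet, pref,
                        SheetMapping(on_unmatched="skip"))
    assert report.rows_read == 2
    assert report.annotations_created == 1
    assert report.unmatched == ["Z99"]
    assert report.annotations_created + len(report.unmatched) == report.rows_read
    with pytest.raises(SheetMatchError):
        load_sheet(store, sheet, pref, SheetMapping(on_unmatched="error"))


def test_missing_key_column(plate, tmp_path):
    store, pref = plate
    sheet = _write(tmp_path / "m.csv", "Pos,K\nA1,v\n")
    with pytest.raises(SheetMappingError):
        load_sheet(store, sheet, pref)


def test_ragged_row_is_parse_error(plate, tmp_path):
    store, pref = plate
    sheet = _write(tmp_path / "m.csv", "Well,K\nA1,v,extra\n")
    with pytest.raises(SheetParseError):
        load_sheet(store, sheet, pref)


def test_address_matching_case_and_padding(plate, tmp_path):
    store, pref = plate
    sheet = _write(tmp_path / "m.csv", "Well,K\na01,x\nP24,y\n")
    report = load_sheet(store, sheet, pref)
    assert report.annotations_created == 2
    assert store.get_annotations(store.well_at(pref, 0, 0))[0][1].pairs == \
        [("K", "x", None)]
    assert store.get_annotations(store.well_at(pref, 15, 23))[0][1].pairs == \
        [("K", "y", None)]


def test_tsv_delimiter_and_bom(plate, tmp_path):
    store, pref = plate
    sheet = tmp_path / "m.tsv"
    sheet.write_bytes("﻿Well\tK\r\nA1\tv\r\n".encode("utf-8"))
    report = load_sheet(store, sheet, pref)
    assert report.annotations_created == 1


def test_export_empty_namespace(plate, tmp_path):
    store, pref = plate
    out = tmp_path / "out.csv"
    assert export_sheet(store, pref, "no-such-ns", out) == 0
    assert out.read_text(encoding="utf-8").strip() == "Well"


def test_export_counts_full_plate(plate, tmp_path):
    store, pref = plate
    p = store.get(pref)
    for (r, c), wref in p.well_refs.items():
        store.annotate(wref, ss.MapAnnotation(
            namespace="ns", pairs=[("K", f"{r}-{c}", None)]))
    assert export_sheet(store, pref, "ns", tmp_path / "out.csv") == 384


def _annotation_multiset(store, pref, namespace):
    out = []
    for wref in store.get(pref).well_refs.values():
        for _, ann in store.get_annotations(wref, namespace=namespace):
            out.append(tuple(ann.pairs))
    return sorted(out)


def test_load_export_load_roundtrip(plate, tmp_path):
    store, pref = plate
    sheet = _write(tmp_path / "m.csv",
                   "Well,Cell line,Temperature [°C],Note\n"
                   "A1,U2OS,37,ok\nB2,HeLa,34,\"has, comma\"\nC3,U2OS,37,\n")
    load_sheet(store, sheet, pref)
    first = _annotation_multiset(store, pref, ss.BULK_NAMESPACE)
    out = tmp_path / "exported.csv"
    export_sheet(store, pref, ss.BULK_NAMESPACE, out)
    with ss.Store(tmp_path / "s2.db") as store2:
        pref2 = store2.create_plate("p", 384)
        load_sheet(store2, out, pref2)
        second = _annotation_multiset(store2, pref2, ss.BULK_NAMESPACE)
    assert first == second != []


def test_roundtrip_preserves_fuzzed_sheets(plate, tmp_path):
    """Seeded fuzz: random keys/values/units survive load->export->load."""
    store, pref = plate
    rng = np.random.default_rng(17)
    keys = ["Cell line", "Dose", "Stain", "Time"]
    units = {"Dose": "mV", "Time": "s"}
    cols = [k for k in keys if rng.random() < 0.9] or keys[:1]
    header = ["Well"] + [f"{k} [{units[k]}]" if k in units else k for k in cols]
    lines = [",".join(header)]
    addresses = [ss.well_address(int(rng.integers(16)), int(rng.integers(24)))
                 for _ in range(30)]
    for i, addr in enumerate(dict.fromkeys(addresses)):
        lines.append(",".join([addr] + [f"v{rng.integers(100)}" for _ in cols]))
    sheet = _write(tmp_path / "fuzz.csv", "\n".join(lines) + "\n")
    r1 = load_sheet(store, sheet, pref)
    first = _annotation_multiset(store, pref, ss.BULK_NAMESPACE)
    out = tmp_path / "fuzz_out.csv"
    assert export_sheet(store, pref, ss.BULK_NAMESPACE, out) == \
        r1.annotations_created
    with ss.Store(tmp_path / "s3.db") as store2:
        pref2 = store2.create_plate("p", 384)
        load_sheet(store2, out, pref2)
        assert _annotation_multiset(store2, pref2, ss.BULK_NAMESPACE) == first


def test_image_level_import(store, tmp_path):
    pref = store.create_plate("p", 96)
    well = store.well_at(pref, 0, 0)
    img = store.add(ss.Image(name="fov-1"))
    store.add_field(well, img)
    sheet = _write(tmp_path / "m.csv", "Image,Focus\nfov-1,good\n")
    report = load_sheet(store, sheet, pref,
                        SheetMapping(target_level="image", key_column="Image"))
    assert report.annotations_created == 1
    (_, ann), = store.get_annotations(img)
    assert ann.pairs == [("Focus", "good", None)]
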