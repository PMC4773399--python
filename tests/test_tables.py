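"""HDF5 feature tables: schema, append/read identity, limited querying."""

import numpy as np
import pytest

import screenstore as ss
from screenstore import tables as tb
from screenstore.errors import (
    BoundsError,
    ColumnNameError,
    ColumnTypeError,
    ConditionError,
    SchemaError,
    ShapeError,
    TableCollisionError,
)
from tests.conftest import random_long_table


def test_wide_schema_has_78_columns():
    schema = ss.example_wide_schema(n_channels=3, n_features=25)
    assert len(schema) == 78  # 3 backlinks + 75 feature columns; >= 53
    assert schema.names[:3] == ["well", "image", "roi"]


def test_single_column_table(tmp_path):
    t = ss.FeatureTable.create(tmp_path / "t.h5",
                               ss.TableSchema([ss.ColumnSpec("v", "float64")]))
    assert t.row_count == 0 and len(t.schema) == 1


def test_duplicate_column_names_rejected():
    with pytest.raises(SchemaError):
        ss.TableSchema([ss.ColumnSpec("a", "int64"), ss.ColumnSpec("a", "float64")])


def test_empty_schema_rejected():
    with pytest.raises(SchemaError):
        ss.TableSchema([])


def test_string_column_needs_width():
    with pytest.raises(SchemaError):
        ss.ColumnSpec("s", "string")
    with pytest.raises(SchemaError):
        ss.ColumnSpec("i", "int64", width=4)


def test_create_collision(tmp_path):
    path = tmp_path / "t.h5"
    ss.FeatureTable.create(path, ss.example_long_schema()).close()
    with pytest.raises(TableCollisionError):
        ss.FeatureTable.create(path, ss.example_long_schema())


def test_append_then_read_identity_across_reopen(tmp_path):
    path = tmp_path / "t.h5"
    schema = ss.TableSchema([
        ss.ColumnSpec("w", "well_ref"), ss.ColumnSpec("n", "int64"),
        ss.ColumnSpec("x", "float64"), ss.ColumnSpec("ok", "bool"),
        ss.ColumnSpec("label", "string", width=12)])
    block = {"w": [1, 2], "n": [10, 20], "x": [0.5, np.nan],
             "ok": [True, False], "label": ["mitotic", "ärrest"]}
    with ss.FeatureTable.create(path, schema) as t:
        assert t.append_rows(block) == (0, 2)
        assert t.append_rows(block) == (2, 2)
    with ss.FeatureTable.open(path) as t:
        assert t.schema == schema
        got = t.read()
        assert got["w"].tolist() == [1, 2, 1, 2]
        assert got["n"].tolist() == [10, 20, 10, 20]
        assert got["x"][0] == 0.5 and np.isnan(got["x"][1])
        assert got["ok"].dtype == bool and got["ok"].tolist() == [True, False] * 2
        assert got["label"].tolist() == ["mitotic", "ärrest"] * 2


def test_zero_length_read_and_bounds(tmp_path):
    t, _ = random_long_table(tmp_path / "t.h5", np.random.default_rng(0), 10)
    got = t.read(["value"], 4, 4)
    assert got["value"].shape == (0,)
    with pytest.raises(BoundsError):
        t.read(["value"], 5, 3)
    with pytest.raises(BoundsError):
        t.read(["value"], 0, 11)
    with pytest.raises(ColumnNameError):
        t.read(["nope"])


def test_missing_column_is_shape_error(tmp_path):
    t = ss.FeatureTable.create(tmp_path / "t.h5", ss.example_long_schema())
    block = {n: [0] for n in t.schema.names if n != "value"}
    with pytest.raises(ShapeError):
        t.append_rows(block)
    assert t.row_count == 0  # failed append leaves the table unchanged


def test_ragged_block_rejected_atomically(tmp_path):
    t = ss.FeatureTable.create(tmp_path / "t.h5", ss.example_long_schema())
    block = {n: [0, 1] for n in t.schema.names}
    block["value"] = [0.0]
    with pytest.raises(ShapeError):
        t.append_rows(block)
    assert t.row_count == 0


@pytest.mark.parametrize("col,bad", [
    ("channel", [0.5]),           # float into int64
    ("channel", [np.nan]),        # no missing representation for int64
    ("value", ["x"]),             # text into float64
    ("roi", [-1]),                # negative object id
])
def test_type_mismatch_rejected(tmp_path, col, bad):
    t = ss.FeatureTable.create(tmp_path / "t.h5", ss.example_long_schema())
    block = {n: [0] for n in t.schema.names}
    block["value"] = [0.0]
    block[col] = bad
    with pytest.raises(ColumnTypeError):
        t.append_rows(block)


def test_string_too_wide_rejected(tmp_path):
    t = ss.FeatureTable.create(
        tmp_path / "t.h5", ss.TableSchema([ss.ColumnSpec("s", "string", width=3)]))
    with pytest.raises(ColumnTypeError):
        t.append_rows({"s": ["abcd"]})
    with pytest.raises(ColumnTypeError):
        t.append_rows({"s": ["°C°C"]})  # 4 UTF-8 bytes > width 3


def test_append_accepts_object_refs(tmp_path):
    t = ss.FeatureTable.create(
        tmp_path / "t.h5", ss.TableSchema([ss.ColumnSpec("w", "well_ref")]))
    t.append_rows({"w": [ss.ObjectRef("well", 7)]})
    assert t.read()["w"].tolist() == [7]
    with pytest.raises(ColumnTypeError):
        t.append_rows({"w": [ss.ObjectRef("image", 7)]})


def test_seeded_append_read_fuzz(tmp_path):
    """100 seeded append/read cycles reproduce every block (shadow-copy oracle)."""
    rng = np.random.default_rng(123)
    t = ss.FeatureTable.create(tmp_path / "t.h5", ss.example_long_schema())
    shadow = {n: [] for n in t.schema.names}
    for _ in range(100):
        n = int(rng.integers(0, 50))
        block = {
            "well": rng.integers(0, 10, n), "image": rng.integers(0, 10, n),
            "roi": rng.integers(0, 100, n), "channel": rng.integers(0, 3, n),
            "feature": rng.integers(0, 25, n), "value": rng.normal(size=n)}
        start, nn = t.append_rows(block)
        assert (start, nn) == (len(shadow["well"]), n)
        for k in shadow:
            shadow[k].extend(np.asarray(block[k]).tolist())
        lo = int(rng.integers(0, len(shadow["well"]) + 1))
        hi = int(rng.integers(lo, len(shadow["well"]) + 1))
        got = t.read(start=lo, stop=hi)
        for k in shadow:
            assert np.array_equal(got[k], np.asarray(shadow[k][lo:hi]))


def test_query_examples(tmp_path):
    t, shadow = random_long_table(tmp_path / "t.h5", np.random.default_rng(7), 1000)
    cond = ss.Condition([("value", ">", 0.5), ("channel", "==", 1)])
    expected = np.nonzero((shadow["value"] > 0.5) & (shadow["channel"] == 1))[0]
    assert np.array_equal(t.query(cond), expected)
    # tautology -> all rows; empty table -> empty
    assert np.array_equal(t.query(ss.Condition([("channel", ">=", 0)])),
                          np.arange(1000))
    t2 = ss.FeatureTable.create(tmp_path / "e.h5", ss.example_long_schema())
    assert t2.query(ss.Condition([("value", ">", 0.0)])).size == 0


@pytest.mark.parametrize("seed", range(6))
def test_query_equals_bruteforce_on_random_tables(tmp_path, seed):
    rng = np.random.default_rng(1000 + seed)
    t, shadow = random_long_table(tmp_path / f"t{seed}.h5", rng,
                                  int(rng.integers(1, 2000)))
    ops = {"==": np.equal, "!=": np.not_equal, "<": np.less, "<=": np.less_equal,
           ">": np.greater, ">=": np.greater_equal}
    for _ in range(20):
        cols = rng.choice(list(shadow), size=rng.integers(1, 3), replace=False)
        terms, mask = [], np.ones(len(shadow["well"]), dtype=bool)
        for col in cols:
            op = list(ops)[rng.integers(len(ops))]
            lit = (float(rng.normal()) if col == "value"
                   else int(rng.integers(0, 5)))
            terms.append((col, op, lit))
            mask &= ops[op](shadow[col], lit)
        assert np.array_equal(t.query(ss.Condition(terms)), np.nonzero(mask)[0])


def test_query_crosses_chunk_boundaries(tmp_path, monkeypatch):
    monkeypatch.setattr(tb, "_CHUNK", 64)
    t, shadow = random_long_table(tmp_path / "t.h5", np.random.default_rng(3), 500)
    cond = ss.Condition([("value", "<", 0.0)])
    assert np.array_equal(t.query(cond), np.nonzero(shadow["value"] < 0.0)[0])


def test_invalid_conditions(tmp_path):
    t, _ = random_long_table(tmp_path / "t.h5", np.random.default_rng(0), 10)
    with pytest.raises(ColumnNameError):
        t.query(ss.Condition([("nope", "==", 1)]))
    with pytest.raises(ConditionError):
        t.query(ss.Condition([("channel", "==", "one")]))
    with pytest.raises(ConditionError):
        ss.Condition([("channel", "~", 1)])


def test_condition_parse():
    c = ss.Condition.parse("(feature_3 > 0.5) AND (channel == 1)")
    assert c.terms == (("feature_3", ">", 0.5), ("channel", "==", 1))
    c2 = ss.Condition.parse("label == 'hit'")
    assert c2.terms == (("label", "==", "hit"),)
    with pytest.raises(ConditionError):
        ss.Condition.parse("feature_3 >")


def test_backlink_equals_ref_query(tmp_path):
    rng = np.random.default_rng(9)
    t, shadow = random_long_table(tmp_path / "t.h5", rng, 800)
    target = ss.ObjectRef("roi", int(shadow["roi"][0]))
    expected = t.query(ss.Condition([("roi", "==", target.oid)]))
    assert np.array_equal(t.backlink("roi", target), expected)
    assert t.backlink("roi", ss.ObjectRef("roi", 10**6)).size == 0
    with pytest.raises(ColumnTypeError):
        t.backlink("roi", ss.ObjectRef("image", 1))
    with pytest.raises(ColumnTypeError):
        t.backlink("value", ss.ObjectRef("roi", 1))


def test_backlink_known_layout(store, tmp_path):
    """50 rows per ROI-group: backlink returns exactly that ROI's rows."""
    img = store.add(ss.Image(name="i"))
    rois = [store.add(ss.ROI(image_ref=img)) for _ in range(4)]
    t = ss.FeatureTable.create(
        tmp_path / "t.h5",
        ss.TableSchema([ss.ColumnSpec("roi", "roi_ref"),
                        ss.ColumnSpec("v", "float64")]))
    for r in rois:
        t.append_rows({"roi": [r.oid] * 50, "v": np.zeros(50)})
    idx = t.backlink("roi", rois[2])
    assert np.array_equal(idx, np.arange(100, 150))


def test_csv_export_roundtrip_values(tmp_path):
    t, shadow = random_long_table(tmp_path / "t.h5", np.random.default_rng(4), 20)
    out = tmp_path / "rows.csv"
    assert t.to_csv(out, 5, 15) == 10
    import csv

    with open(out, encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    assert rows[0] == t.schema.names
    assert [float(r[-1]) for r in rows[1:]] == shadow["value"][5:15].tolist()
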