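"""Group permission rules and their enforcement on every read surface."""

import numpy as np
import pytest

import screenstore as ss
import screenstore.search_index as search_mod
from screenstore.errors import AccessError, PolicyError
from screenstore.permissions import LEVELS, Ownership, can_annotate, can_read

OWNER = ss.Principal("alice", frozenset({"lab"}))
MEMBER = ss.Principal("bob", frozenset({"lab"}))
NON_MEMBER = ss.Principal("eve", frozenset({"other"}))
ADMIN = ss.Principal("root", frozenset(), True)

OWN = Ownership("alice", "lab")

# (level, principal) -> (can_read, can_annotate): the full truth table
TRUTH = {
    ("private", "owner"): (True, True),
    ("private", "member"): (False, False),
    ("private", "non-member"): (False, False),
    ("group_read", "owner"): (True, True),
    ("group_read", "member"): (True, False),
    ("group_read", "non-member"): (False, False),
    ("group_read_annotate", "owner"): (True, True),
    ("group_read_annotate", "member"): (True, True),
    ("group_read_annotate", "non-member"): (False, False),
    ("public_read", "owner"): (True, True),
    ("public_read", "member"): (True, False),
    ("public_read", "non-member"): (True, False),
}
WHO = {"owner": OWNER, "member": MEMBER, "non-member": NON_MEMBER}


@pytest.mark.parametrize("level", LEVELS)
@pytest.mark.parametrize("rel", list(WHO))
def test_rule_truth_table(level, rel):
    expect_read, expect_annotate = TRUTH[(level, rel)]
    assert can_read(WHO[rel], OWN, level) is expect_read
    assert can_annotate(WHO[rel], OWN, level) is expect_annotate
    # admin can always do both
    assert can_read(ADMIN, OWN, level) and can_annotate(ADMIN, OWN, level)


def test_read_permission_monotone_in_level():
    for rel, p in WHO.items():
        reads = [can_read(p, OWN, lv) for lv in LEVELS]
        # once readable, raising the level never revokes it
        assert reads == sorted(reads)


@pytest.fixture
def shared_store(tmp_path):
    with ss.Store(tmp_path / "s.db", default_owner="alice",
                  default_group="lab") as st:
        yield st


def _store_truth_obj(shared_store, level):
    shared_store.set_group_policy("lab", level)
    return shared_store.add(ss.Reagent(identifier="cmpd"))


@pytest.mark.parametrize("level", LEVELS)
@pytest.mark.parametrize("rel", list(WHO))
def test_store_enforces_truth_table(shared_store, level, rel):
    ref = _store_truth_obj(shared_store, level)
    assert shared_store.can_read(ref, WHO[rel]) is TRUTH[(level, rel)][0]
    assert shared_store.can_annotate(ref, WHO[rel]) is TRUTH[(level, rel)][1]


def test_reassign_owner_workflow(shared_store):
    """Facility manager imports a plate, then hands it to the scientist."""
    manager = ss.Principal("manager", frozenset({"facility"}), True)
    plate = shared_store.create_plate("run-42", 96, owner="manager",
                                      group="facility")
    scientist = ss.Principal("carol", frozenset())
    assert not shared_store.can_read(plate, scientist)  # private, not hers
    own = shared_store.reassign_owner(plate, "carol", actor=manager)
    assert own.owner == "carol"
    assert shared_store.can_read(plate, scientist)
    # the previous owner is now an outsider to a private group object
    assert not shared_store.can_read(
        plate, ss.Principal("manager", frozenset(), False))


def test_reassign_requires_owner_or_admin(shared_store):
    ref = shared_store.add(ss.Reagent(identifier="x"))
    with pytest.raises(AccessError):
        shared_store.reassign_owner(ref, "eve", actor=NON_MEMBER)
    shared_store.reassign_owner(ref, "bob", actor=OWNER)  # owner may
    assert shared_store.ownership(ref).owner == "bob"


def test_policy_cannot_be_lowered_with_data(shared_store):
    shared_store.set_group_policy("lab", "public_read")
    shared_store.add(ss.Reagent(identifier="x"))
    with pytest.raises(PolicyError):
        shared_store.set_group_policy("lab", "private")
    shared_store.set_group_policy("empty-group", "public_read")
    shared_store.set_group_policy("empty-group", "private")  # no data: fine


def test_private_object_invisible_on_every_surface(shared_store, tmp_path):
    """A non-member must not reach a private object via annotations, table
    reads, backlinks, or search."""
    st = shared_store  # level defaults to private
    plate = st.create_plate("secret", 96)
    well = st.well_at(plate, 0, 0)
    st.annotate(well, ss.MapAnnotation(pairs=[("Cell line", "U2OS", None)]),
                as_user=OWNER)
    table_path = tmp_path / "t.h5"
    t = ss.FeatureTable.create(
        table_path, ss.TableSchema([ss.ColumnSpec("well", "well_ref"),
                                    ss.ColumnSpec("v", "float64")]))
    t.append_rows({"well": [well.oid], "v": [1.0]})
    t.close()
    table_ref = st.register_table(table_path, link_to=plate)

    # annotations surface
    with pytest.raises(AccessError):
        st.get_annotations(well, as_user=NON_MEMBER)
    assert st.query_map("Cell line", as_user=NON_MEMBER) == []
    # object fetch
    with pytest.raises(AccessError):
        st.get(well, as_user=NON_MEMBER)
    # table surface (read and backlink go through open_table)
    with pytest.raises(AccessError):
        st.open_table(table_ref, as_user=NON_MEMBER)
    # search surface
    search_mod.reindex(st)
    assert search_mod.search(st, "U2OS", caller=NON_MEMBER) == []
    assert search_mod.search(st, "secret", caller=NON_MEMBER) == []

    # the same calls succeed for the owner
    assert st.get_annotations(well, as_user=OWNER)
    assert st.query_map("Cell line", as_user=OWNER)
    with st.open_table(table_ref, as_user=OWNER) as tt:
        assert np.array_equal(tt.backlink("well", well), [0])
    assert search_mod.search(st, "U2OS", caller=OWNER)


def test_public_read_opens_reads_not_annotation(shared_store):
    shared_store.set_group_policy("lab", "public_read")
    plate = shared_store.create_plate("open", 96)
    well = shared_store.well_at(plate, 0, 0)
    shared_store.annotate(well, ss.TagAnnotation(text="hit"), as_user=OWNER)
    assert shared_store.get_annotations(well, as_user=NON_MEMBER)
    with pytest.raises(AccessError):
        shared_store.annotate(well, ss.TagAnnotation(text="nope"),
                              as_user=NON_MEMBER)


def test_unlinked_table_is_owner_private(shared_store, tmp_path):
    t = ss.FeatureTable.create(
        tmp_path / "t.h5", ss.TableSchema([ss.ColumnSpec("v", "float64")]))
    t.close()
    ref = shared_store.register_table(tmp_path / "t.h5", owner="alice")
    shared_store.set_group_policy("lab", "public_read")
    assert shared_store.can_read(ref, OWNER)
    # table ownership group is "default" (unlinked), so even lab members fail
    assert not shared_store.can_read(ref, MEMBER)
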