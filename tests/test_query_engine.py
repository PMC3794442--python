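"""SQL-free search: matching semantics, the brute-force oracle, cursors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eventstore as es
from _oracle import brute_force_query, dump_for_oracle


# ---------------------------------------------------------------------------
# Pure matching semantics

class TestMatchStrings:
    @pytest.mark.parametrize("cell,qual,regexp,expected", [
        ("www.cs.utsa.edu", "www.cs.utsa.edu", False, True),
        ("restricted", ["www.cs.utsa.edu", "restricted"], False, True),
        ("eeg_data_ch1", ["eeg.*"], True, True),
        ("my_eeg_data", ["eeg.*"], True, False),  # patterns anchor at start
        ("other", ["www.cs.utsa.edu", "restricted"], False, False),
    ])
    def test_direct_list_and_regex_modes(self, cell, qual, regexp, expected):
        assert es.match_strings(cell, qual, regexp) is expected

    def test_invalid_pattern_raises(self):
        with pytest.raises(es.QueryError):
            es.match_strings("x", ["("], regexp=True)


class TestMatchTagGroups:
    def test_and_of_groups_or_within_group(self):
        tags = {"EyeTrack", "AudioLeft"}
        groups = ["EyeTrack", ["VisualTarget", "Audio.*"]]
        assert es.match_tag_groups(tags, groups, regexp=True)
        assert not es.match_tag_groups({"AudioLeft"}, groups, regexp=True)

    def test_empty_group_list_matches_everything(self):
        assert es.match_tag_groups(set(), [])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_agrees_with_brute_force_evaluator(self, data):
        vocab = ["a", "ab", "abc", "b", "bc", "Audio", "AudioLeft"]
        tags = set(data.draw(st.lists(st.sampled_from(vocab), max_size=5)))
        groups = data.draw(st.lists(
            st.one_of(st.sampled_from(vocab + ["a.*", "Audio.*"]),
                      st.lists(st.sampled_from(vocab + ["b.*"]),
                               min_size=1, max_size=3)),
            max_size=3))
        regexp = data.draw(st.booleans())

        import re
        def member_ok(tag, m):
            return re.match(m, tag) is not None if regexp else tag == m

        expected = all(
            any(member_ok(t, m) for t in tags
                for m in (g if isinstance(g, list) else [g]))
            for g in groups
        )
        assert es.match_tag_groups(tags, groups, regexp) is expected


# ---------------------------------------------------------------------------
# Templates and put_rows

class TestTemplates:
    def test_dataset_template_matches_column_set(self, conn):
        template = es.get_template(conn, "datasets")
        assert set(template) == {
            "dataset_uuid", "dataset_session_uuid", "dataset_namespace",
            "dataset_name", "dataset_version", "dataset_contact_uuid",
            "dataset_creation_date", "dataset_description",
            "dataset_parent_uuid", "dataset_modality_uuid", "dataset_oid"}
        assert all(v is None for v in template.values())

    def test_event_template_has_timing_and_certainty_fields(self, conn):
        template = es.get_template(conn, "events")
        for col in ("event_start_time", "event_end_time", "event_certainty",
                    "event_type_uuid"):
            assert col in template

    def test_limit_zero_query_returns_the_template(self, conn):
        rows = es.get_rows(conn, es.QuerySpec(table="events", limit=0))
        assert rows == [es.get_template(conn, "events")]

    def test_unknown_table_rejected(self, conn):
        with pytest.raises(es.QueryError):
            es.get_template(conn, "nope")


class TestPutRows:
    def test_insert_returns_fresh_uuids(self, conn):
        uuids = es.put_rows(conn, "event_types", [
            {"event_type": "a"}, {"event_type": "b"}, {"event_type": "c"}])
        assert len(set(uuids)) == 3
        assert len(es.get_rows(conn, es.QuerySpec(table="event_types"))) == 3

    def test_update_by_primary_key_changes_one_row(self, conn):
        uid, _ = es.store_dataset(conn, es.DatasetRecord(
            name="d", data=b"x", modality="SIMPLE"))
        es.put_rows(conn, "datasets", [
            {"dataset_uuid": uid, "dataset_description": "updated"}])
        (row,) = es.get_rows(conn, es.QuerySpec(
            table="datasets", column_quals={"dataset_uuid": uid}))
        assert row["dataset_description"] == "updated"
        assert row["dataset_name"] == "d"

    def test_unknown_column_fails_whole_batch(self, conn):
        with pytest.raises(es.QueryError):
            es.put_rows(conn, "event_types", [
                {"event_type": "ok"}, {"bogus": 1}])
        assert es.get_rows(conn, es.QuerySpec(table="event_types")) == []

    def test_type_mismatch_rejected(self, conn):
        with pytest.raises(es.QueryError):
            es.put_rows(conn, "events", [{"event_start_time": "not-a-number"}])


# ---------------------------------------------------------------------------
# Randomized database + oracle equivalence

NAMESPACES = ["mobbed", "www.cs.utsa.edu", "restricted"]
TAG_VOCAB = ["EyeTrack", "VisualTarget", "AudioLeft", "AudioRight",
             "/Context/Indoors/Simulator/Driving", "/Context/Participants/Alone",
             "Driving", "Child", "Focused"]
ATTR_PATHS = ["/event/target_dist", "/chanlocs/1/X", "/meta/site"]


def populate_random(conn, rng, n_datasets=40):
    """Random datasets with random tags and attributes, plus event types."""
    for i in range(n_datasets):
        name = rng.choice(["eeg_data", "eeg_run", "meg_run", "sim"]) + f"_ch{i}"
        uid, _ = es.store_dataset(
            conn,
            es.DatasetRecord(name=name, data=b"x", modality="SIMPLE",
                             namespace=str(rng.choice(NAMESPACES))),
            es.StoreOptions(is_unique=False),
        )
        ref = es.EntityRef(uid, "datasets")
        tags = rng.choice(TAG_VOCAB, size=rng.integers(0, 5), replace=False)
        if len(tags):
            es.add_tags(conn, ref, [str(t) for t in tags])
        for _ in range(rng.integers(0, 3)):
            path = str(rng.choice(ATTR_PATHS))
            if rng.random() < 0.5:
                es.add_attribute(conn, ref, path, float(rng.integers(0, 20)))
            else:
                es.add_attribute(conn, ref, path, str(rng.choice(["a", "b"])))
    es.put_rows(conn, "event_types",
                [{"event_type": f"type_{i:02d}"} for i in range(8)])


def random_spec(rng, table="datasets"):
    quals = {}
    regexp = bool(rng.random() < 0.5)
    if table == "datasets":
        r = rng.random()
        if r < 0.3:
            quals["dataset_namespace"] = str(rng.choice(NAMESPACES))
        elif r < 0.5:
            quals["dataset_name"] = (["eeg.*", "sim.*"] if regexp
                                     else ["eeg_data_ch1", "sim_ch3"])
        elif r < 0.6:
            quals["dataset_version"] = int(rng.integers(1, 4))
    else:
        if rng.random() < 0.5:
            quals["event_type"] = (["type_0.*"] if regexp
                                   else [f"type_{rng.integers(0, 8):02d}"])
    def group():
        members = rng.choice(TAG_VOCAB + ["Audio.*", "/Context/.*"],
                             size=rng.integers(1, 4), replace=False)
        return [str(m) for m in members] if len(members) > 1 else str(members[0])
    tag_groups = [group() for _ in range(rng.integers(0, 3))]
    attr_groups = []
    if rng.random() < 0.3:
        attr_groups = [[str(rng.choice(ATTR_PATHS + ["/event/.*", "12.0"]))]]
    limit = ["all", int(rng.integers(1, 30))][rng.integers(0, 2)]
    return es.QuerySpec(table=table, limit=limit, column_quals=quals,
                        tag_groups=tag_groups, attribute_groups=attr_groups,
                        regexp=regexp)


def assert_matches_oracle(conn, spec):
    rows, pk, types, tags_by, attrs_by = dump_for_oracle(conn, spec.table)
    limit = None if spec.limit == "all" else spec.limit
    expected = brute_force_query(
        rows, pk, types, tags_by, attrs_by, spec.column_quals,
        spec.tag_groups, spec.attribute_groups, spec.regexp, limit)
    got = [r[pk] for r in es.get_rows(conn, spec)]
    assert got == expected


class TestOracleEquivalence:
    def test_no_qualification_returns_every_row(self, conn):
        rng = np.random.default_rng(11)
        populate_random(conn, rng, n_datasets=10)
        rows = es.get_rows(conn, es.QuerySpec(table="datasets"))
        assert len(rows) == 10

    def test_worked_tag_example(self, conn):
        uid1, _ = es.store_dataset(conn, es.DatasetRecord(
            name="match", data=b"x", modality="SIMPLE"))
        es.add_tags(conn, es.EntityRef(uid1, "datasets"),
                    ["EyeTrack", "AudioLeft"])
        uid2, _ = es.store_dataset(conn, es.DatasetRecord(
            name="nomatch", data=b"x", modality="SIMPLE"))
        es.add_tags(conn, es.EntityRef(uid2, "datasets"), ["AudioLeft"])
        spec = es.QuerySpec(table="datasets",
                            tag_groups=["EyeTrack", ["VisualTarget", "Audio.*"]],
                            regexp=True)
        assert [r["dataset_uuid"] for r in es.get_rows(conn, spec)] == [uid1]
        assert_matches_oracle(conn, spec)

    def test_three_tag_conjunction(self, conn):
        uid, _ = es.store_dataset(conn, es.DatasetRecord(
            name="all3", data=b"x", modality="SIMPLE"))
        es.add_tags(conn, es.EntityRef(uid, "datasets"),
                    ["Driving", "Child", "Focused"])
        uid2, _ = es.store_dataset(conn, es.DatasetRecord(
            name="two", data=b"x", modality="SIMPLE"))
        es.add_tags(conn, es.EntityRef(uid2, "datasets"), ["Driving", "Child"])
        rows = es.get_rows(conn, es.QuerySpec(
            table="datasets", tag_groups=["Driving", "Child", "Focused"]))
        assert [r["dataset_uuid"] for r in rows] == [uid]

    def test_one_hundred_randomized_specs_match_oracle(self, conn):
        rng = np.random.default_rng(2024)
        populate_random(conn, rng)
        for _ in range(100):
            table = str(rng.choice(["datasets", "event_types"]))
            assert_matches_oracle(conn, random_spec(rng, table))

    def test_limit_k_is_prefix_of_limit_k_plus_one(self, conn):
        rng = np.random.default_rng(7)
        populate_random(conn, rng, n_datasets=15)
        for k in (1, 5, 14):
            a = es.get_rows(conn, es.QuerySpec(table="datasets", limit=k))
            b = es.get_rows(conn, es.QuerySpec(table="datasets", limit=k + 1))
            assert b[:len(a)] == a

    def test_unknown_column_rejected(self, conn):
        with pytest.raises(es.QueryError):
            es.get_rows(conn, es.QuerySpec(table="datasets",
                                           column_quals={"nope": 1}))

    def test_uuid_columns_never_use_regex(self, conn):
        uid, _ = es.store_dataset(conn, es.DatasetRecord(
            name="u", data=b"x", modality="SIMPLE"))
        rows = es.get_rows(conn, es.QuerySpec(
            table="datasets", column_quals={"dataset_uuid": ".*"},
            regexp=True))
        assert rows == []  # '.*' is an exact value here, not a pattern


# ---------------------------------------------------------------------------
# Cursors

def _store_events(conn, n):
    g = es.GenericStruct(event=[
        {"type": "t", "start_time": float(i), "end_time": float(i)}
        for i in range(n)])
    uid, _ = es.store_dataset(conn, es.DatasetRecord(
        name="big", data=g, modality="GENERIC"))
    return uid


class TestCursors:
    def test_250_rows_partition_into_100_100_50_then_empty(self, conn):
        _store_events(conn, 250)
        spec = es.QuerySpec(table="events")
        batch, _state = es.open_cursor(conn, spec, "mycursor", 100)
        sizes = [len(batch)]
        seen = [r["event_uuid"] for r in batch]
        while batch:
            batch = es.fetch_next(conn, "mycursor")
            sizes.append(len(batch))
            seen.extend(r["event_uuid"] for r in batch)
        assert sizes == [100, 100, 50, 0]
        full = [r["event_uuid"] for r in es.get_rows(conn, spec)]
        assert seen == full
        assert len(set(seen)) == len(seen)

    def test_zero_matches_gives_empty_first_batch(self, conn):
        batch, _ = es.open_cursor(
            conn, es.QuerySpec(table="events"), "empty", 10)
        assert batch == []
        assert es.fetch_next(conn, "empty") == []

    def test_cursor_respects_overall_limit(self, conn):
        _store_events(conn, 30)
        batch, _ = es.open_cursor(
            conn, es.QuerySpec(table="events", limit=25), "lim", 10)
        total = len(batch)
        while batch:
            batch = es.fetch_next(conn, "lim")
            total += len(batch)
        assert total == 25

    def test_duplicate_cursor_name_and_unknown_cursor_error(self, conn):
        es.open_cursor(conn, es.QuerySpec(table="events"), "c1", 10)
        with pytest.raises(es.UniquenessError):
            es.open_cursor(conn, es.QuerySpec(table="events"), "c1", 10)
        with pytest.raises(es.QueryError):
            es.fetch_next(conn, "never-opened")
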