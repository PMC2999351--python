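import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromine.datashare import (AuthorizationError, NotFoundError, ShareStore)

TS = "2009-01-01T00:00:00+00:00"  # fixed timestamps keep stores comparable


@pytest.fixture
def store():
    s = ShareStore(":memory:")
    s.add_user("alice", ["neuro"])
    s.add_user("bob", [])
    s.add_user("carol", ["neuro", "other"])
    s.add_user("dave", ["other"])
    yield s
    s.close()


def make_ds(store, rows=(("1001",), ("1002",), ("1003",)), user="alice"):
    return store.create_dataset(user, "pmids", ["pmid"], list(rows),
                                application="app", parameters="q=schizophrenia",
                                timestamp=TS)


class TestCreateAndGet:
    def test_round_trip_in_row_order(self, store):
        ds = make_ds(store)
        defn, rows = store.get_dataset("alice", ds)
        assert rows == [["1001"], ["1002"], ["1003"]]
        assert defn.field_names == ("pmid",)
        assert defn.creator == "alice"

    def test_wrong_arity_stores_nothing(self, store):
        with pytest.raises(ValueError, match="arity|values"):
            store.create_dataset("alice", "bad", ["a", "b"], [["only-one"]],
                                 application="app")
        with pytest.raises(NotFoundError):
            store.get_dataset("alice", 1)

    def test_create_history_is_single_create_event(self, store):
        ds = make_ds(store)
        (ev,) = store.history(ds)
        assert (ev.sequence_number, ev.change_type) == (1, "create")
        assert ev.application == "app"

    def test_duplicate_or_empty_field_names_rejected(self, store):
        with pytest.raises(ValueError):
            store.create_dataset("alice", "t", [], [], application="app")
        with pytest.raises(ValueError):
            store.create_dataset("alice", "t", ["a", "a"], [], application="app")

    def test_unknown_dataset(self, store):
        with pytest.raises(NotFoundError):
            store.get_dataset("alice", 99)


class TestPermissions:
    def test_truth_table_eight_cases(self, store):
        """Access for {creator, user-granted, group-granted, stranger} x
        {private, public} equals the hand-written table."""
        ds = make_ds(store)
        store.set_permission("alice", ds, "user:bob")
        store.set_permission("alice", ds, "group:neuro")

        def readable(u):
            try:
                store.get_dataset(u, ds)
                return True
            except AuthorizationError:
                return False

        # private: creator yes, granted user yes, group member yes, stranger no
        assert [readable(u) for u in ("alice", "bob", "carol", "dave")] == \
            [True, True, True, False]
        store.set_permission("alice", ds, "public")
        assert [readable(u) for u in ("alice", "bob", "carol", "dave")] == \
            [True, True, True, True]

    def test_public_readable_by_anonymous(self, store):
        ds = make_ds(store)
        with pytest.raises(AuthorizationError):
            store.get_dataset(None, ds)
        store.set_permission("alice", ds, "public")
        _, rows = store.get_dataset(None, ds)
        assert rows

    def test_only_creator_may_grant(self, store):
        ds = make_ds(store)
        with pytest.raises(AuthorizationError):
            store.set_permission("bob", ds, "public")

    def test_grant_is_idempotent_and_revocable(self, store):
        ds = make_ds(store)
        store.set_permission("alice", ds, "user:bob")
        store.set_permission("alice", ds, "user:bob")
        store.get_dataset("bob", ds)
        store.revoke_permission("alice", ds, "user:bob")
        with pytest.raises(AuthorizationError):
            store.get_dataset("bob", ds)

    def test_malformed_principal_rejected(self, store):
        ds = make_ds(store)
        with pytest.raises(ValueError):
            store.set_permission("alice", ds, "everyone")

    @settings(max_examples=40, derandomize=True)
    @given(
        grants=st.sets(
            st.sampled_from(["user:bob", "user:carol", "group:neuro",
                             "group:other", "public"]),
            max_size=5),
        caller=st.sampled_from(["alice", "bob", "carol", "dave", None]),
    )
    def test_never_leaks_beyond_truth_table(self, grants, caller):
        store = ShareStore(":memory:")
        store.add_user("alice", ["neuro"])
        store.add_user("bob", [])
        store.add_user("carol", ["neuro", "other"])
        store.add_user("dave", ["other"])
        groups = {"alice": {"neuro"}, "bob": set(),
                  "carol": {"neuro", "other"}, "dave": {"other"}}
        ds = make_ds(store)
        for g in grants:
            store.set_permission("alice", ds, g)
        allowed = (
            caller == "alice"
            or "public" in grants
            or (caller is not None and f"user:{caller}" in grants)
            or (caller is not None
                and any(f"group:{g}" in grants for g in groups[caller]))
        )
        try:
            store.get_dataset(caller, ds)
            got = True
        except AuthorizationError:
            got = False
        store.close()
        assert got == allowed


class TestUpdateAndHistory:
    def test_update_appends_event(self, store):
        ds = make_ds(store)
        store.update_dataset("alice", ds, [["2001"]], "app", timestamp=TS)
        evs = store.history(ds)
        assert len(evs) == 2 and evs[-1].change_type == "update"
        _, rows = store.get_dataset("alice", ds)
        assert rows == [["2001"]]

    def test_append_preserves_order(self, store):
        ds = make_ds(store)
        store.update_dataset("alice", ds, [["2001"], ["2002"]], "app",
                             append=True, timestamp=TS)
        _, rows = store.get_dataset("alice", ds)
        assert rows == [["1001"], ["1002"], ["1003"], ["2001"], ["2002"]]

    def test_non_creator_cannot_write(self, store):
        ds = make_ds(store)
        with pytest.raises(AuthorizationError):
            store.update_dataset("bob", ds, [["x"]], "app")
        with pytest.raises(AuthorizationError):
            store.delete_dataset("bob", ds, "app")

    def test_delete_is_logical_with_event(self, store):
        ds = make_ds(store)
        store.delete_dataset("alice", ds, "app", timestamp=TS)
        with pytest.raises(NotFoundError):
            store.get_dataset("alice", ds)
        assert store.history(ds)[-1].change_type == "delete"
        _, deleted = store.replay(ds)
        assert deleted

    def test_replay_reconstructs_random_op_sequences(self, store):
        rng = np.random.default_rng(13)
        ds = make_ds(store)
        deleted = False
        for step in range(20):
            op = rng.choice(["update", "append", "delete", "recreate"])
            if deleted and op != "recreate":
                continue
            rows = [[str(int(v))] for v in rng.integers(0, 9999, rng.integers(0, 4))]
            if op == "update" and not deleted:
                store.update_dataset("alice", ds, rows, "app", timestamp=TS)
            elif op == "append" and not deleted:
                store.update_dataset("alice", ds, rows, "app", append=True,
                                     timestamp=TS)
            elif op == "delete" and not deleted:
                store.delete_dataset("alice", ds, "app", timestamp=TS)
                deleted = True
            elif op == "recreate":
                ds = make_ds(store, rows=[["7"]])
                deleted = False
            if not deleted:
                _, current = store.get_dataset("alice", ds)
                replayed, dead = store.replay(ds)
                assert not dead and replayed == current
        seqs = [e.sequence_number for e in store.history(ds)]
        assert seqs == list(range(1, len(seqs) + 1))


class TestExchange:
    def test_export_import_export_is_byte_identical(self, store, tmp_path):
        ds = make_ds(store)
        store.set_permission("alice", ds, "public")
        doc = store.export_json(None, ds)
        fresh = ShareStore(str(tmp_path / "fresh.db"))
        ds2 = fresh.import_json(doc, application="other-app", timestamp=TS)
        assert fresh.export_json("alice", ds2) == doc
        fresh.close()
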