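import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parwire.connection_store import (
    ConnectionRecord,
    ConnectionStore,
    ConnectorPolicy,
    LocalityError,
    export_edges_tsv,
    make_stores,
    read_edges_tsv,
)
from parwire.topology import ParallelLayout


def fresh_store(vp=0, VP=1, K_cutoff=3):
    layout = ParallelLayout(VP, 1)
    return ConnectionStore(vp, layout, ConnectorPolicy(K_cutoff=K_cutoff))


class TestConnectorStateMachine:
    def test_first_connection(self):
        store = fresh_store()
        store.add_connection(5, 0, "static")
        connector = store.table[5]
        assert connector.kind == "hom_fixed"
        assert connector.size == 1
        assert (store.ledger.n_alloc, store.ledger.n_free) == (2, 1)

    def test_three_connections_become_dynamic(self):
        store = fresh_store()
        for _ in range(3):
            store.add_connection(5, 0, "static")
        connector = store.table[5]
        assert connector.kind == "hom_dynamic"
        assert next(iter(connector.subs.values())).capacity == 3
        assert (store.ledger.n_alloc, store.ledger.n_free) == (4, 3)

    def test_52_connections_ledger(self):
        # derived by per-step rule replay; equals 4+ceil(log2(52/3)) = 9 allocs
        store = fresh_store()
        for _ in range(52):
            store.add_connection(5, 0, "static")
        assert (store.ledger.n_alloc, store.ledger.n_free) == (9, 8)

    def test_two_types_heterogeneous(self):
        store = fresh_store()
        store.add_connection(5, 0, "type_a")
        store.add_connection(5, 0, "type_b")
        connector = store.table[5]
        assert connector.kind == "heterogeneous"
        assert [sub.size for sub in connector.subs.values()] == [1, 1]

    def test_dynamic_capacities_are_cutoff_doublings(self):
        store = fresh_store()
        seen = set()
        for _ in range(100):
            store.add_connection(5, 0, "static")
            sub = next(iter(store.table[5].subs.values()))
            if sub.dynamic:
                seen.add(sub.capacity)
        assert seen <= {3, 6, 12, 24, 48, 96, 192}

    @pytest.mark.parametrize("k", range(1, 11))
    @pytest.mark.parametrize("n_types", [1, 2])
    def test_kind_is_pure_function_of_count_and_types(self, k, n_types):
        # exhaustive over counts 1..10 x types 1..2, arrival orders shuffled
        rng = random.Random(k * 10 + n_types)
        for trial in range(5):
            types = [f"t{i % n_types}" for i in range(k)]
            if n_types == 2 and k >= 2:
                types[0], types[1] = "t0", "t1"  # force both types present
            rng.shuffle(types)
            if n_types == 2 and k >= 2 and len(set(types)) == 1:
                types[-1] = "t1" if types[0] == "t0" else "t0"
            store = fresh_store()
            for t in types:
                store.add_connection(7, 0, t)
            connector = store.table[7]
            if n_types == 2 and k >= 2:
                assert connector.kind == "heterogeneous"
            elif k < 3:
                assert connector.kind == "hom_fixed"
            else:
                assert connector.kind == "hom_dynamic"
            assert connector.size == k

    def test_locality_violation(self):
        store = fresh_store(vp=0, VP=2)
        with pytest.raises(LocalityError):
            store.add_connection(0, 1, "static")  # gid 1 belongs to vp 1


class TestTargetsOf:
    def test_unset_source_empty(self):
        assert fresh_store().targets_of(42) == []

    def test_order_preserved(self):
        store = fresh_store()
        for i in range(7):
            store.add_connection(3, 0, "static", weight=float(i))
        weights = [r.weight for r in store.targets_of(3)]
        assert weights == [float(i) for i in range(7)]

    def test_type_filter(self):
        store = fresh_store()
        store.add_connection(3, 0, "a")
        store.add_connection(3, 0, "b")
        store.add_connection(3, 0, "a")
        assert len(store.targets_of(3, "a")) == 2
        assert len(store.targets_of(3, "b")) == 1

    def test_concatenation_matches_bookkeeping_oracle(self):
        rng = random.Random(4)
        store = fresh_store(vp=0, VP=3)
        inserted = []
        for _ in range(200):
            source = rng.randrange(20)
            syn = rng.choice(["a", "b"])
            store.add_connection(source, rng.randrange(0, 30, 3), syn)
            inserted.append(source)
        total = sum(len(store.targets_of(s)) for s in range(20))
        assert total == 200
        for s in range(20):
            assert len(store.targets_of(s)) == inserted.count(s)


class TestCensus:
    def test_empty(self):
        assert fresh_store().occupancy_census(100) == (100, 0, 0)

    def test_matches_event_log_oracle(self):
        rng = random.Random(9)
        store = fresh_store()
        tally = {}
        for _ in range(300):
            s = rng.randrange(50)
            store.add_connection(s, 0, "static")
            tally[s] = tally.get(s, 0) + 1
        n0 = 50 - len(tally)
        n1 = sum(1 for v in tally.values() if v == 1)
        n_more = sum(1 for v in tally.values() if v > 1)
        assert store.occupancy_census(50) == (n0, n1, n_more)

    def test_census_sums_to_total(self):
        store = fresh_store()
        for s in range(5):
            store.add_connection(s, 0, "static")
        n0, n1, n_more = store.occupancy_census(12)
        assert n0 + n1 + n_more == 12


class TestLedger:
    @given(st.lists(st.sampled_from(["a", "b"]), min_size=1, max_size=60))
    @settings(max_examples=100)
    def test_alloc_always_ahead_of_free(self, types):
        store = fresh_store()
        for t in types:
            store.add_connection(1, 0, t)
            assert store.ledger.n_alloc >= store.ledger.n_free
        # surviving containers: allocs minus frees is positive
        assert store.ledger.n_alloc > store.ledger.n_free

    def test_event_log_sequencing(self):
        store = fresh_store(vp=0)
        store.add_connection(1, 0, "a")
        kinds = [e[1] for e in store.ledger.events]
        assert kinds.count("alloc") == 2 and kinds.count("free") == 1
        assert [e[2] for e in store.ledger.events] == sorted(
            e[2] for e in store.ledger.events
        )

    def test_record_events_off_keeps_counts(self):
        layout = ParallelLayout(1, 1)
        store = ConnectionStore(0, layout, record_events=False)
        for _ in range(10):
            store.add_connection(2, 0, "a")
        assert store.ledger.events == []
        assert store.ledger.n_alloc == 6  # 4 + ceil(log2(10/3))

    def test_invalid_policy(self):
        with pytest.raises(ValueError):
            ConnectorPolicy(K_cutoff=1)
        with pytest.raises(ValueError):
            ConnectorPolicy(growth_factor=1)


class TestRecordValidation:
    def test_nonpositive_delay_rejected(self):
        with pytest.raises(ValueError):
            ConnectionRecord(target=0, synapse_type="a", delay=0.0)


class TestExport:
    def test_roundtrip(self, tmp_path):
        layout = ParallelLayout(2, 1)
        stores = make_stores(layout)
        rng = random.Random(3)
        for _ in range(50):
            t = rng.randrange(10)
            stores[t % 2].add_connection(rng.randrange(10), t, rng.choice(["a", "b"]))
        path = tmp_path / "edges.tsv"
        export_edges_tsv(stores, path)
        rows = read_edges_tsv(path)
        assert len(rows) == 50
        # census of a store rebuilt from the file matches the original union
        rebuilt = make_stores(layout)
        for source, rec in rows:
            rebuilt[rec.target % 2].add_connection(
                source, rec.target, rec.synapse_type, rec.weight, rec.delay
            )
        for vp in (0, 1):
            assert rebuilt[vp].occupancy_census(10) == stores[vp].occupancy_census(10)
        assert [r[0] for r in rows] == sorted(r[0] for r in rows)
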