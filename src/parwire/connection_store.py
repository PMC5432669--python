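"""Per-VP adjacency storage: sparse source table + adaptive connectors.

Each virtual process stores every connection whose target it owns, in a
hierarchy keyed by source gid.  A source with no local targets costs one
unset presence bit.  Otherwise its connector is, depending on the number of
local connections k and the number of distinct synapse types:

* ``hom_fixed``   — 1 <= k < K_cutoff, one type: fixed-size array, replaced
  wholesale on each growth;
* ``hom_dynamic`` — k >= K_cutoff, one type: dynamically sized, capacity
  K_cutoff * 2**j, doubling when full;
* ``heterogeneous`` — >= 2 types: one homogeneous sub-connector per type.

Every modeled allocation/free event is appended to an
:class:`AllocationLedger`, reproducing the construction-time accounting:
first connection of a source costs one connector allocation plus one
alloc + one free for sparse-table registration; each fixed-size growth,
the transition to dynamic, each capacity doubling, and the heterogeneous
conversion each cost one alloc + one free; a new sub-connector costs one
alloc.  The ledger models accounting only — no real heap behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple


class LocalityError(ValueError):
    """Connection added on a VP that does not own the target."""


@dataclass(frozen=True)
class ConnectorPolicy:
    """Container-selection thresholds for connectors."""

    K_cutoff: int = 3
    growth_factor: int = 2

    def __post_init__(self) -> None:
        if self.K_cutoff < 2:
            raise ValueError("K_cutoff must be >= 2")
        if self.growth_factor <= 1:
            raise ValueError("growth_factor must be > 1")


@dataclass(frozen=True)
class ConnectionRecord:
    target: int
    synapse_type: str
    weight: float = 1.0
    delay: float = 1.5

    def __post_init__(self) -> None:
        if self.delay <= 0:
            raise ValueError(f"delay must be positive, got {self.delay}")


@dataclass
class AllocationLedger:
    """Counts (and optionally an ordered log) of modeled alloc/free events."""

    n_alloc: int = 0
    n_free: int = 0
    vp: int = 0
    record_events: bool = True
    events: List[Tuple[int, str, int]] = field(default_factory=list)
    _seq: int = 0

    def alloc(self) -> None:
        self.n_alloc += 1
        if self.record_events:
            self.events.append((self.vp, "alloc", self._seq))
        self._seq += 1

    def free(self) -> None:
        if self.n_free >= self.n_alloc:
            raise RuntimeError("ledger invariant violated: free before alloc")
        self.n_free += 1
        if self.record_events:
            self.events.append((self.vp, "free", self._seq))
        self._seq += 1

    @property
    def total_events(self) -> int:
        return self.n_alloc + self.n_free


class _HomConnector:
    """Homogeneous connector for a single synapse type."""

    __slots__ = ("synapse_type", "records", "capacity", "dynamic")

    def __init__(self, synapse_type: str):
        self.synapse_type = synapse_type
        self.records: List[ConnectionRecord] = []
        self.capacity = 1
        self.dynamic = False

    def append(self, record: ConnectionRecord, policy: ConnectorPolicy, ledger: AllocationLedger) -> None:
        """Add one record, advancing the container state machine."""
        k_old = len(self.records)
        if k_old == 0:
            # fresh one-element connector
            ledger.alloc()
            self.capacity = 1
        elif not self.dynamic:
            if k_old + 1 < policy.K_cutoff:
                # replace fixed-size connector with one of size k_old + 1
                ledger.alloc()
                ledger.free()
                self.capacity = k_old + 1
            else:
                # transition to dynamically sized container
                ledger.alloc()
                ledger.free()
                self.dynamic = True
                self.capacity = policy.K_cutoff
        elif k_old + 1 > self.capacity:
            # capacity doubling
            ledger.alloc()
            ledger.free()
            self.capacity *= policy.growth_factor
        self.records.append(record)

    @property
    def size(self) -> int:
        return len(self.records)


class Connector:
    """Per-source connector: homogeneous, or heterogeneous with one
    homogeneous sub-connector per synapse type (insertion-ordered)."""

    __slots__ = ("subs",)

    def __init__(self) -> None:
        self.subs: Dict[str, _HomConnector] = {}

    @property
    def heterogeneous(self) -> bool:
        return len(self.subs) > 1

    @property
    def size(self) -> int:
        return sum(sub.size for sub in self.subs.values())

    @property
    def kind(self) -> str:
        if self.heterogeneous:
            return "heterogeneous"
        sub = next(iter(self.subs.values()))
        return "hom_dynamic" if sub.dynamic else "hom_fixed"

    def add(self, record: ConnectionRecord, policy: ConnectorPolicy, ledger: AllocationLedger) -> None:
        sub = self.subs.get(record.synapse_type)
        if sub is None:
            if self.subs:
                # conversion to heterogeneous connector: cost equal to
                # sparse-table registration (one alloc + one free)
                ledger.alloc()
                ledger.free()
            sub = self.subs[record.synapse_type] = _HomConnector(record.synapse_type)
        sub.append(record, policy, ledger)

    def iter_records(self, synapse_type: Optional[str] = None) -> Iterator[ConnectionRecord]:
        if synapse_type is not None:
            sub = self.subs.get(synapse_type)
            if sub is not None:
                yield from sub.records
            return
        for sub in self.subs.values():
            yield from sub.records


class ConnectionStore:
    """All incoming connections of one virtual process.

    The sparse source table is realized as a dict keyed by source gid: key
    presence is the presence bit; registration of a fresh key models the
    sparse-table update (one alloc + one free).
    """

    def __init__(
        self,
        vp: int,
        layout,
        policy: ConnectorPolicy = ConnectorPolicy(),
        record_events: bool = True,
    ):
        from .topology import assign_vp  # local import to avoid cycle at module load

        self.vp = vp
        self.layout = layout
        self.policy = policy
        self.ledger = AllocationLedger(vp=vp, record_events=record_events)
        self.table: Dict[int, Connector] = {}
        self.local_nodes: List[int] = []
        self.n_connections = 0
        self._assign_vp = assign_vp

    def add_connection(
        self,
        source: int,
        target: int,
        synapse_type: str,
        weight: float = 1.0,
        delay: float = 1.5,
    ) -> None:
        if self._assign_vp(target, self.layout) != self.vp:
            raise LocalityError(
                f"target {target} is not local to vp {self.vp} "
                f"(owner: vp {self._assign_vp(target, self.layout)})"
            )
        record = ConnectionRecord(target=target, synapse_type=synapse_type, weight=weight, delay=delay)
        connector = self.table.get(source)
        if connector is None:
            connector = self.table[source] = Connector()
            # sparse-table registration of the fresh source
            self.ledger.alloc()
            self.ledger.free()
        connector.add(record, self.policy, self.ledger)
        self.n_connections += 1

    def targets_of(self, source: int, synapse_type: Optional[str] = None) -> List[ConnectionRecord]:
        connector = self.table.get(source)
        if connector is None:
            return []
        return list(connector.iter_records(synapse_type))

    def has_source(self, source: int) -> bool:
        return source in self.table

    def local_degree(self, source: int) -> int:
        connector = self.table.get(source)
        return 0 if connector is None else connector.size

    def occupancy_census(self, total_sources: int) -> Tuple[int, int, int]:
        """Counts of sources (over ``[0, total_sources)``) with 0, 1 and >1
        local connections."""
        n1 = 0
        n_more = 0
        for source, connector in self.table.items():
            if source >= total_sources:
                continue
            k = connector.size
            if k == 1:
                n1 += 1
            elif k > 1:
                n_more += 1
        n0 = total_sources - n1 - n_more
        return n0, n1, n_more

    def iter_edges(self) -> Iterator[Tuple[int, ConnectionRecord]]:
        """(source, record) pairs sorted by source, insertion order within."""
        for source in sorted(self.table):
            for record in self.table[source].iter_records():
                yield source, record


def make_stores(
    layout,
    policy: ConnectorPolicy = ConnectorPolicy(),
    record_events: bool = True,
    vps: Optional[List[int]] = None,
) -> Dict[int, ConnectionStore]:
    """One store per virtual process (or per listed vp for dryruns)."""
    if vps is None:
        vps = list(range(layout.VP))
    return {vp: ConnectionStore(vp, layout, policy, record_events) for vp in vps}


def export_edges_tsv(stores: Dict[int, ConnectionStore], path) -> None:
    """Write all stored records as TSV: source, target, synapse_type, weight,
    delay; rows sorted by (source, insertion order) within each store, stores
    in vp order."""
    rows: List[Tuple[int, int, int, ConnectionRecord]] = []
    for vp in sorted(stores):
        store = stores[vp]
        for idx, (source, record) in enumerate(store.iter_edges()):
            rows.append((source, vp, idx, record))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write("source\ttarget\tsynapse_type\tweight\tdelay\n")
        for source, _vp, _idx, record in rows:
            fh.write(
                f"{source}\t{record.target}\t{record.synapse_type}\t"
                f"{record.weight:g}\t{record.delay:g}\n"
            )


def read_edges_tsv(path) -> List[Tuple[int, ConnectionRecord]]:
    """Read an edge-list TSV back as (source, record) pairs in file order."""
    out: List[Tuple[int, ConnectionRecord]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["source", "target", "synapse_type", "weight", "delay"]:
            raise ValueError(f"unexpected edge-list header {header!r} in {path}")
        for line in fh:
            src, tgt, syn, w, d = line.rstrip("\n").split("\t")
            out.append(
                (int(src), ConnectionRecord(int(tgt), syn, float(w), float(d)))
            )
    return out
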