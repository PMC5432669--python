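"""Population-level wiring: fixed in-degree in two loop orders, all-to-all.

The fixed in-degree rule gives every target exactly K connections whose
sources are i.i.d. uniform over the source set (with replacement; autapses
permitted).  Two loop orders build identical networks:

* *target scan* — every VP iterates the whole target set and skips
  non-local targets (outer work proportional to |targets| per VP);
* *local scan*  — every VP iterates only its own local nodes and tests
  membership in the target set (outer work proportional to |targets| / VP).

Both visit local targets in ascending gid order, so they consume per-VP
random streams identically and produce identical stores.  Per-phase
operation counters stand in for phase timings: iteration, source selection
and connection instantiation are counted separately.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

from .connection_store import ConnectionStore
from .rng_streams import VpRngSuite, draw_uniform_indices
from .topology import GidRange, ParallelLayout, assign_vp

GidSet = Union[range, GidRange, Sequence[int]]

TARGET_SCAN = "target-scan"
LOCAL_SCAN = "local-scan"
LOOP_ORDERS = (TARGET_SCAN, LOCAL_SCAN)


@dataclass(frozen=True)
class SynapseSpec:
    synapse_type: str = "static"
    weight: float = 1.0
    delay: float = 1.5


@dataclass(frozen=True)
class ConnRequest:
    """One collective connect call."""

    source_set: GidSet
    target_set: GidSet
    rule: str = "fixed_in_degree"
    K: int = 0
    synapse_spec: SynapseSpec = SynapseSpec()

    def __post_init__(self) -> None:
        if self.rule not in ("fixed_in_degree", "all_to_all"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if len(as_sequence(self.source_set)) == 0 or len(as_sequence(self.target_set)) == 0:
            raise ValueError("source and target sets must be non-empty")


@dataclass
class PhaseCounters:
    """Hardware-independent surrogate for per-phase construction timings."""

    outer_iterations: int = 0
    nonlocal_skips: int = 0
    source_draws: int = 0
    connect_calls: int = 0
    membership_tests: int = 0

    def as_dict(self) -> Dict[str, int]:
        return {
            "outer_iterations": self.outer_iterations,
            "nonlocal_skips": self.nonlocal_skips,
            "source_draws": self.source_draws,
            "connect_calls": self.connect_calls,
            "membership_tests": self.membership_tests,
        }

    def merge(self, other: "PhaseCounters") -> None:
        self.outer_iterations += other.outer_iterations
        self.nonlocal_skips += other.nonlocal_skips
        self.source_draws += other.source_draws
        self.connect_calls += other.connect_calls
        self.membership_tests += other.membership_tests


def as_sequence(gid_set: GidSet) -> Sequence[int]:
    """Indexable ascending view of a gid set."""
    if isinstance(gid_set, GidRange):
        return range(gid_set.first, gid_set.stop)
    return gid_set


def membership(target_set: GidSet, gid: int) -> bool:
    """Constant-cost for contiguous ranges, logarithmic for sorted lists."""
    if isinstance(target_set, GidRange):
        return target_set.first <= gid < target_set.stop
    if isinstance(target_set, range):
        # caller contract: step-1 ranges only
        return target_set.start <= gid < target_set.stop
    idx = bisect_left(target_set, gid)
    return idx < len(target_set) and target_set[idx] == gid


def _connect_k_sources(
    store: ConnectionStore,
    target: int,
    sources: Sequence[int],
    K: int,
    spec: SynapseSpec,
    suite: VpRngSuite,
    counters: PhaseCounters,
) -> None:
    stream = suite.stream(store.vp)
    idx = draw_uniform_indices(stream, len(sources), K)
    counters.source_draws += K
    add = store.add_connection
    for i in idx:
        add(sources[i], target, spec.synapse_type, spec.weight, spec.delay)
    counters.connect_calls += K


def connect_fixed_in_degree_target_scan(
    request: ConnRequest,
    stores: Dict[int, ConnectionStore],
    suite: VpRngSuite,
    layout: ParallelLayout,
) -> Dict[int, PhaseCounters]:
    """Listing-style loop order: every VP scans all targets."""
    if request.rule != "fixed_in_degree":
        raise ValueError("rule must be fixed_in_degree")
    sources = as_sequence(request.source_set)
    targets = as_sequence(request.target_set)
    counters = {vp: PhaseCounters() for vp in stores}
    for vp, store in stores.items():
        c = counters[vp]
        for target in targets:
            c.outer_iterations += 1
            if assign_vp(target, layout) != vp:
                c.nonlocal_skips += 1
                continue
            _connect_k_sources(store, target, sources, request.K, request.synapse_spec, suite, c)
    return counters


def connect_fixed_in_degree_local_scan(
    request: ConnRequest,
    stores: Dict[int, ConnectionStore],
    suite: VpRngSuite,
    layout: ParallelLayout,
    local_nodes: Optional[Dict[int, List[int]]] = None,
) -> Dict[int, PhaseCounters]:
    """Reversed loop order: every VP iterates only its local nodes and tests
    target membership."""
    if request.rule != "fixed_in_degree":
        raise ValueError("rule must be fixed_in_degree")
    sources = as_sequence(request.source_set)
    counters = {vp: PhaseCounters() for vp in stores}
    for vp, store in stores.items():
        c = counters[vp]
        nodes = store.local_nodes if local_nodes is None else local_nodes[vp]
        for node in nodes:
            c.outer_iterations += 1
            c.membership_tests += 1
            if not membership(request.target_set, node):
                continue
            _connect_k_sources(store, node, sources, request.K, request.synapse_spec, suite, c)
    return counters


def connect_all_to_all(
    request: ConnRequest,
    stores: Dict[int, ConnectionStore],
    layout: ParallelLayout,
    loop_order: str = TARGET_SCAN,
    local_nodes: Optional[Dict[int, List[int]]] = None,
) -> Dict[int, PhaseCounters]:
    """One connection from every source to every target; no randomness."""
    if request.rule != "all_to_all":
        raise ValueError("rule must be all_to_all")
    if loop_order not in LOOP_ORDERS:
        raise ValueError(f"loop_order must be one of {LOOP_ORDERS}")
    sources = as_sequence(request.source_set)
    targets = as_sequence(request.target_set)
    spec = request.synapse_spec
    counters = {vp: PhaseCounters() for vp in stores}
    for vp, store in stores.items():
        c = counters[vp]
        if loop_order == TARGET_SCAN:
            outer = targets
        else:
            outer = store.local_nodes if local_nodes is None else local_nodes[vp]
        for target in outer:
            c.outer_iterations += 1
            if loop_order == TARGET_SCAN:
                if assign_vp(target, layout) != vp:
                    c.nonlocal_skips += 1
                    continue
            else:
                c.membership_tests += 1
                if not membership(request.target_set, target):
                    continue
            for source in sources:
                store.add_connection(source, target, spec.synapse_type, spec.weight, spec.delay)
                c.connect_calls += 1
    return counters


def connect(
    request: ConnRequest,
    stores: Dict[int, ConnectionStore],
    suite: VpRngSuite,
    layout: ParallelLayout,
    loop_order: str = TARGET_SCAN,
    local_nodes: Optional[Dict[int, List[int]]] = None,
) -> Dict[int, PhaseCounters]:
    """Dispatch a request to the matching rule/loop-order implementation."""
    if request.rule == "all_to_all":
        return connect_all_to_all(request, stores, layout, loop_order, local_nodes)
    if loop_order == TARGET_SCAN:
        return connect_fixed_in_degree_target_scan(request, stores, suite, layout)
    return connect_fixed_in_degree_local_scan(request, stores, suite, layout, local_nodes)
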