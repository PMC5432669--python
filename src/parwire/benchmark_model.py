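"""Builder for the balanced random network benchmark at configurable scale.

Population layout (0-based gids): excitatory neurons first (``eps*N``), then
inhibitory neurons, then one external-drive device and one spike recorder.
Each neuron receives exactly ``n_E = eps*K`` connections from random
excitatory sources and ``n_I = (1-eps)*K`` from random inhibitory sources.
Excitatory-to-excitatory synapses use a plastic type and
excitatory-to-inhibitory a static excitatory type, which forces
heterogeneous connectors for excitatory sources; all inhibitory-source
synapses share a single static inhibitory type.  Devices are connected
all-to-all and stored apart from the neuron adjacency so that the neuron
ledger and census follow the neuron-only accounting.

Two build modes:

* ``full``  — every connection goes through the connector state machine and
  allocation ledger (per-connection Python cost; use for small builds or
  single-rank dryruns);
* ``count`` — identical random draws, but only per-source tallies are kept
  (vectorized; ledgers unavailable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .connection_rules import (
    TARGET_SCAN,
    ConnRequest,
    PhaseCounters,
    SynapseSpec,
    connect,
    membership,
)
from .connection_store import ConnectionStore, ConnectorPolicy, make_stores
from .predictions import NetworkSpec
from .rng_streams import VpRngSuite, draw_uniform_indices, make_suite
from .topology import (
    GidRange,
    ModelRegistry,
    ParallelLayout,
    create_nodes,
    local_gids,
)

SYN_EE = "stdp_exc"
SYN_EI = "static_exc"
SYN_INH = "static_inh"
SYN_DEVICE = "static_device"


@dataclass(frozen=True)
class HpcBenchmarkSpec:
    """Balanced random network benchmark parameters."""

    net: NetworkSpec
    weight_exc: float = 0.1
    weight_inh: float = -0.5
    delay_ms: float = 1.5
    drive_rate_hz: float = 8000.0
    duration_ms: float = 100.0

    def __post_init__(self) -> None:
        for name, value in (
            ("eps*N", self.net.epsilon * self.net.N),
            ("eps*K", self.net.epsilon * self.net.K),
        ):
            if abs(value - round(value)) > 1e-9:
                raise ValueError(f"population split {name} = {value} is not integral")

    @property
    def N_E(self) -> int:
        return round(self.net.epsilon * self.net.N)

    @property
    def N_I(self) -> int:
        return self.net.N - self.N_E

    @property
    def n_E(self) -> int:
        return round(self.net.epsilon * self.net.K)

    @property
    def n_I(self) -> int:
        return self.net.K - self.n_E


@dataclass
class BuildResult:
    """Everything a benchmark build produces besides the stores themselves."""

    layout: ParallelLayout
    seed: int
    loop_order: str
    mode: str
    registry: ModelRegistry = field(default_factory=ModelRegistry)
    neuron_range: Optional[GidRange] = None
    exc_range: Optional[GidRange] = None
    inh_range: Optional[GidRange] = None
    drive_gid: int = -1
    recorder_gid: int = -1
    stores: Optional[Dict[int, ConnectionStore]] = None
    device_stores: Optional[Dict[int, ConnectionStore]] = None
    counters: Dict[int, PhaseCounters] = field(default_factory=dict)
    device_counters: Dict[int, PhaseCounters] = field(default_factory=dict)
    ledgers: Dict[int, Tuple[int, int]] = field(default_factory=dict)
    census: Dict[int, Tuple[int, int, int]] = field(default_factory=dict)
    n_neuron_connections: int = 0
    n_device_connections: int = 0
    local_nodes: Dict[int, List[int]] = field(default_factory=dict)

    def report(self) -> dict:
        return {
            "layout": {"M": self.layout.M, "T": self.layout.T, "VP": self.layout.VP},
            "seed": self.seed,
            "loop_order": self.loop_order,
            "mode": self.mode,
            "totals": {
                "neuron_connections": self.n_neuron_connections,
                "device_connections": self.n_device_connections,
            },
            "per_vp": {
                str(vp): {
                    "phases": self.counters[vp].as_dict(),
                    "device_phases": (
                        self.device_counters[vp].as_dict()
                        if vp in self.device_counters
                        else None
                    ),
                    "ledger": (
                        {"n_alloc": self.ledgers[vp][0], "n_free": self.ledgers[vp][1]}
                        if vp in self.ledgers
                        else None
                    ),
                    "census": list(self.census[vp]) if vp in self.census else None,
                }
                for vp in sorted(self.counters)
            },
        }


def _requests(bench: HpcBenchmarkSpec, result: BuildResult) -> List[ConnRequest]:
    exc, inh, neurons = result.exc_range, result.inh_range, result.neuron_range
    return [
        ConnRequest(
            source_set=exc, target_set=exc, rule="fixed_in_degree", K=bench.n_E,
            synapse_spec=SynapseSpec(SYN_EE, bench.weight_exc, bench.delay_ms),
        ),
        ConnRequest(
            source_set=exc, target_set=inh, rule="fixed_in_degree", K=bench.n_E,
            synapse_spec=SynapseSpec(SYN_EI, bench.weight_exc, bench.delay_ms),
        ),
        ConnRequest(
            source_set=inh, target_set=neurons, rule="fixed_in_degree", K=bench.n_I,
            synapse_spec=SynapseSpec(SYN_INH, bench.weight_inh, bench.delay_ms),
        ),
    ]


def _create_populations(bench: HpcBenchmarkSpec, result: BuildResult, vps: List[int]) -> None:
    reg, layout = result.registry, result.layout
    result.exc_range = create_nodes(reg, "iaf_exc", bench.N_E, layout)
    result.inh_range = create_nodes(reg, "iaf_inh", bench.N_I, layout)
    result.neuron_range = GidRange(0, bench.net.N, "neurons")
    result.drive_gid = create_nodes(reg, "poisson_drive", 1, layout).first
    result.recorder_gid = create_nodes(reg, "spike_recorder", 1, layout).first
    for vp in vps:
        nodes: List[int] = []
        for entry in reg.entries:
            nodes.extend(local_gids(vp, entry, layout))
        result.local_nodes[vp] = sorted(nodes)


def _connect_devices_full(
    bench: HpcBenchmarkSpec,
    result: BuildResult,
    device_stores: Dict[int, ConnectionStore],
) -> None:
    layout = result.layout
    drive_req = ConnRequest(
        source_set=[result.drive_gid], target_set=result.neuron_range,
        rule="all_to_all",
        synapse_spec=SynapseSpec(SYN_DEVICE, bench.weight_exc, bench.delay_ms),
    )
    rec_req = ConnRequest(
        source_set=result.neuron_range, target_set=[result.recorder_gid],
        rule="all_to_all",
        synapse_spec=SynapseSpec(SYN_DEVICE, 1.0, bench.delay_ms),
    )
    for req in (drive_req, rec_req):
        counters = connect(
            req, device_stores, None, layout,
            loop_order=result.loop_order, local_nodes=result.local_nodes,
        )
        for vp, c in counters.items():
            result.device_counters.setdefault(vp, PhaseCounters()).merge(c)
    result.n_device_connections = sum(s.n_connections for s in device_stores.values())


def build_benchmark(
    bench: HpcBenchmarkSpec,
    layout: ParallelLayout,
    seed: int = 12345,
    loop_order: str = TARGET_SCAN,
    mode: str = "full",
    vps: Optional[List[int]] = None,
    record_events: bool = False,
    policy: ConnectorPolicy = ConnectorPolicy(),
    connect_devices: bool = True,
) -> BuildResult:
    """Construct the benchmark network on the given (or all) virtual
    processes.  Per-VP results depend only on (spec, VP, seed), never on the
    (M, T) split or on which other VPs are built alongside."""
    if mode not in ("full", "count"):
        raise ValueError("mode must be 'full' or 'count'")
    if vps is None:
        vps = list(range(layout.VP))
    result = BuildResult(layout=layout, seed=seed, loop_order=loop_order, mode=mode)
    _create_populations(bench, result, vps)
    suite = make_suite(seed, layout)
    requests = _requests(bench, result)

    if mode == "full":
        stores = make_stores(layout, policy, record_events, vps)
        for vp in vps:
            stores[vp].local_nodes = result.local_nodes[vp]
        for req in requests:
            counters = connect(
                req, stores, suite, layout,
                loop_order=loop_order, local_nodes=result.local_nodes,
            )
            for vp, c in counters.items():
                result.counters.setdefault(vp, PhaseCounters()).merge(c)
        result.stores = stores
        result.n_neuron_connections = sum(s.n_connections for s in stores.values())
        for vp in vps:
            result.ledgers[vp] = (stores[vp].ledger.n_alloc, stores[vp].ledger.n_free)
            result.census[vp] = stores[vp].occupancy_census(bench.net.N)
        if connect_devices:
            device_stores = make_stores(layout, policy, record_events, vps)
            _connect_devices_full(bench, result, device_stores)
            result.device_stores = device_stores
    else:
        _build_count_mode(bench, result, suite, requests, vps, connect_devices)
    return result


def _build_count_mode(
    bench: HpcBenchmarkSpec,
    result: BuildResult,
    suite: VpRngSuite,
    requests: List[ConnRequest],
    vps: List[int],
    connect_devices: bool,
) -> None:
    """Same draws as the full build, tallies only (vectorized)."""
    layout = result.layout
    local_scan = result.loop_order != TARGET_SCAN
    total = 0
    for vp in vps:
        c = PhaseCounters()
        stream = suite.stream(vp)
        draw_chunks: List[np.ndarray] = []
        for req in requests:
            src = req.source_set
            src_first, src_len = src.first, src.count
            if local_scan:
                for node in result.local_nodes[vp]:
                    c.outer_iterations += 1
                    c.membership_tests += 1
                    if not membership(req.target_set, node):
                        continue
                    idx = draw_uniform_indices(stream, src_len, req.K)
                    draw_chunks.append(idx + src_first)
                    c.source_draws += req.K
                    c.connect_calls += req.K
            else:
                for target in range(req.target_set.first, req.target_set.stop):
                    c.outer_iterations += 1
                    if target % layout.VP != vp:
                        c.nonlocal_skips += 1
                        continue
                    idx = draw_uniform_indices(stream, src_len, req.K)
                    draw_chunks.append(idx + src_first)
                    c.source_draws += req.K
                    c.connect_calls += req.K
        result.counters[vp] = c
        if draw_chunks:
            all_draws = np.concatenate(draw_chunks)
            _, counts = np.unique(all_draws, return_counts=True)
            n1 = int(np.count_nonzero(counts == 1))
            n_more = len(counts) - n1
            result.census[vp] = (bench.net.N - n1 - n_more, n1, n_more)
            total += int(all_draws.size)
        else:
            result.census[vp] = (bench.net.N, 0, 0)
    result.n_neuron_connections = total
    if connect_devices:
        # drive -> every neuron (on the neuron's VP); every neuron -> recorder
        drive_edges = sum(
            sum(1 for g in result.local_nodes[vp] if g < bench.net.N) for vp in vps
        )
        rec_vp = result.recorder_gid % layout.VP
        rec_edges = bench.net.N if rec_vp in vps else 0
        result.n_device_connections = drive_edges + rec_edges


def dryrun_build(
    bench: HpcBenchmarkSpec,
    total_processes: int,
    threads: int,
    rank: int,
    seed: int = 12345,
    loop_order: str = TARGET_SCAN,
    mode: str = "full",
    **kwargs,
) -> BuildResult:
    """Emulate one MPI rank of an M-process x T-thread run: build only that
    rank's T virtual processes.  Identical per-VP results to a full build."""
    layout = ParallelLayout(total_processes, threads)
    vps = layout.vps_of_rank(rank)
    return build_benchmark(
        bench, layout, seed=seed, loop_order=loop_order, mode=mode, vps=vps, **kwargs
    )
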