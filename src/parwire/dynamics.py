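"""Minimal time-driven dynamics over a constructed adjacency.

Leaky integrate-and-fire neurons with exponentially decaying synaptic
current, delayed spike delivery through the connection stores, and an
optional additive pair-based plasticity rule.  The loop exists to
demonstrate that the stores support state propagation and that results are
invariant under the process/thread factorization: per time step, each VP
updates its local neurons in ascending gid order and draws external Poisson
input from its own stream, so spike records depend only on (network, seed,
VP count).

Membrane update per step (exact exponential relaxation, current held
constant over the step)::

    V <- V_inf + (V - V_inf) * exp(-dt/tau_m),   V_inf = E_L + R*(I_syn + I_ext)

Spike when V >= V_th, then V = V_reset and the neuron is refractory for
t_ref.  All delays must be integer multiples of dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .connection_store import ConnectionStore
from .rng_streams import VpRngSuite
from .topology import GidRange


class DiscretizationError(ValueError):
    """A delay is not an integer multiple of the step size."""


@dataclass(frozen=True)
class LifParams:
    tau_m: float = 20.0      # ms
    E_L: float = 0.0         # mV
    V_th: float = 20.0       # mV
    V_reset: float = 0.0     # mV
    t_ref: float = 2.0       # ms
    R: float = 1.0           # membrane resistance (mV per current unit)
    tau_syn: float = 0.5     # ms


@dataclass
class NeuronState:
    V: float
    refractory_left: int = 0
    I_syn: float = 0.0


@dataclass(frozen=True)
class SpikeRecord:
    time: float  # ms
    gid: int


@dataclass(frozen=True)
class StdpParams:
    A_plus: float = 0.01
    A_minus: float = 0.01
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    w_min: float = 0.0
    w_max: float = 10.0


def stdp_update(
    weight: float,
    pre_times: Sequence[float],
    post_times: Sequence[float],
    params: StdpParams = StdpParams(),
) -> float:
    """Additive all-pairs spike-timing-dependent weight update.

    Causal pairs (pre before post, lag d > 0) potentiate by
    ``A_plus * exp(-d/tau_plus)``; anti-causal pairs depress by
    ``A_minus * exp(-d/tau_minus)``; coincident spikes contribute nothing.
    The result is clipped to [w_min, w_max].
    """
    dw = 0.0
    for tp in pre_times:
        for tq in post_times:
            d = tq - tp
            if d > 0:
                dw += params.A_plus * math.exp(-d / params.tau_plus)
            elif d < 0:
                dw -= params.A_minus * math.exp(d / params.tau_minus)
    return min(params.w_max, max(params.w_min, weight + dw))


def _steps(value_ms: float, dt: float, what: str) -> int:
    steps = value_ms / dt
    if abs(steps - round(steps)) > 1e-9:
        raise DiscretizationError(f"{what} {value_ms} ms is not a multiple of dt={dt} ms")
    return round(steps)


def simulate(
    stores: Dict[int, ConnectionStore],
    neuron_range: GidRange,
    duration_ms: float,
    dt_ms: float = 0.1,
    suite: Optional[VpRngSuite] = None,
    params: LifParams = LifParams(),
    initial_V: Optional[Dict[int, float]] = None,
    I_ext: float = 0.0,
    drive_rate_hz: float = 0.0,
    drive_weight: float = 0.0,
) -> List[SpikeRecord]:
    """Advance the network state for ``duration_ms`` and return all spikes
    sorted by (time, gid).

    ``I_ext`` is a constant external current into every neuron;
    ``drive_rate_hz`` adds per-neuron independent Poisson input of weight
    ``drive_weight`` drawn from the owning VP's stream.
    """
    n_steps = _steps(duration_ms, dt_ms, "duration")
    alpha = math.exp(-dt_ms / params.tau_m)
    beta = math.exp(-dt_ms / params.tau_syn)
    ref_steps = _steps(params.t_ref, dt_ms, "refractory period")
    rate_per_step = drive_rate_hz * dt_ms / 1000.0

    # local neurons per vp, ascending; delay horizon from the stored records
    vp_neurons: Dict[int, List[int]] = {}
    max_delay_steps = 1
    for vp, store in stores.items():
        if store.local_nodes:
            vp_neurons[vp] = [g for g in store.local_nodes if g in neuron_range]
        else:
            from .topology import local_gids

            vp_neurons[vp] = list(local_gids(vp, neuron_range, store.layout))
        for _src, rec in store.iter_edges():
            max_delay_steps = max(max_delay_steps, _steps(rec.delay, dt_ms, "delay"))
    horizon = max_delay_steps + 1

    states: Dict[int, NeuronState] = {}
    buffers: Dict[int, List[float]] = {}
    for vp in sorted(stores):
        for gid in vp_neurons[vp]:
            v0 = params.E_L if initial_V is None else initial_V.get(gid, params.E_L)
            states[gid] = NeuronState(V=v0)
            buffers[gid] = [0.0] * horizon

    spikes: List[SpikeRecord] = []
    for step in range(n_steps):
        t = (step + 1) * dt_ms  # spike timestamps at end of step
        slot = step % horizon
        step_spikes: List[int] = []
        for vp in sorted(stores):
            stream = suite.stream(vp) if suite is not None else None
            for gid in vp_neurons[vp]:
                st = states[gid]
                st.I_syn = st.I_syn * beta + buffers[gid][slot]
                buffers[gid][slot] = 0.0
                if stream is not None and rate_per_step > 0.0:
                    st.I_syn += drive_weight * int(stream.poisson(rate_per_step))
                if st.refractory_left > 0:
                    st.refractory_left -= 1
                    st.V = params.V_reset
                    continue
                v_inf = params.E_L + params.R * (st.I_syn + I_ext)
                st.V = v_inf + (st.V - v_inf) * alpha
                if st.V >= params.V_th:
                    st.V = params.V_reset
                    st.refractory_left = ref_steps
                    step_spikes.append(gid)
                    spikes.append(SpikeRecord(time=t, gid=gid))
        # delayed delivery through the adjacency
        for source in step_spikes:
            for vp, store in stores.items():
                for rec in store.targets_of(source):
                    if rec.target not in buffers:
                        continue
                    d = _steps(rec.delay, dt_ms, "delay")
                    buffers[rec.target][(step + d) % horizon] += rec.weight
    spikes.sort(key=lambda s: (s.time, s.gid))
    return spikes


def write_gdf(spikes: Sequence[SpikeRecord], path) -> None:
    """Plain-text spike file: one ``time_ms<TAB>gid`` line per spike, sorted
    by time then gid."""
    with open(path, "w") as fh:
        for s in spikes:
            fh.write(f"{s.time:.3f}\t{s.gid}\n")


def read_gdf(path) -> List[SpikeRecord]:
    out: List[SpikeRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            t, g = line.split("\t")
            out.append(SpikeRecord(time=float(t), gid=int(g)))
    return out
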