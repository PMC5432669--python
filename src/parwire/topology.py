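"""Global node enumeration and round-robin distribution over virtual processes.

Nodes (neurons and devices) are enumerated by 0-based global identifiers
(gids) and distributed over ``VP = M * T`` virtual processes round-robin:
``vp = gid % VP``.  Only the vp identity matters for any construction
result, so any fixed bijection vp -> (process, thread) is admissible; here
``process = vp % M`` and ``thread = vp // M``.

Non-local nodes are never materialized individually: a :class:`ModelRegistry`
records one :class:`GidRange` per create call, so registry size is
independent of population size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional


class LayoutError(ValueError):
    """Invalid process/thread decomposition."""


class EmptyPopulationError(ValueError):
    """A create call with zero nodes."""


@dataclass(frozen=True)
class ParallelLayout:
    """An ``M``-process x ``T``-thread decomposition into ``VP = M * T``
    virtual processes."""

    M: int
    T: int

    def __post_init__(self) -> None:
        if self.M < 1 or self.T < 1:
            raise LayoutError(
                f"process/thread counts must be positive, got M={self.M}, T={self.T}"
            )

    @property
    def VP(self) -> int:
        return self.M * self.T

    def vp_to_process_thread(self, vp: int) -> tuple[int, int]:
        """Fixed bijection vp -> (process, thread)."""
        if not 0 <= vp < self.VP:
            raise LayoutError(f"vp {vp} out of range for VP={self.VP}")
        return vp % self.M, vp // self.M

    def vps_of_rank(self, rank: int) -> List[int]:
        """All vp indices hosted by MPI rank ``rank`` (ascending)."""
        if not 0 <= rank < self.M:
            raise LayoutError(f"rank {rank} out of range for M={self.M}")
        return [rank + t * self.M for t in range(self.T)]


@dataclass(frozen=True)
class GidRange:
    """A contiguous half-open block ``[first, first+count)`` of gids sharing
    one node model."""

    first: int
    count: int
    model_id: str

    @property
    def stop(self) -> int:
        return self.first + self.count

    def __contains__(self, gid: int) -> bool:
        return self.first <= gid < self.stop

    def __iter__(self) -> Iterator[int]:
        return iter(range(self.first, self.stop))


def assign_vp(gid: int, layout: ParallelLayout) -> int:
    """Virtual process owning ``gid``: round-robin ``gid % VP``."""
    if gid < 0:
        raise ValueError(f"gid must be non-negative, got {gid}")
    return gid % layout.VP


def local_gids(vp: int, rng: GidRange, layout: ParallelLayout) -> range:
    """Gids of ``rng`` owned by ``vp``, ascending (stride ``VP``)."""
    VP = layout.VP
    if not 0 <= vp < VP:
        raise LayoutError(f"vp {vp} out of range for VP={VP}")
    # first gid >= rng.first congruent to vp modulo VP
    offset = (vp - rng.first) % VP
    start = rng.first + offset
    if start >= rng.stop:
        return range(start, start, VP)
    return range(start, rng.stop, VP)


def local_count(vp: int, rng: GidRange, layout: ParallelLayout) -> int:
    """Number of gids of ``rng`` local to ``vp`` (no iteration)."""
    return len(local_gids(vp, rng, layout))


@dataclass
class ModelRegistry:
    """Ordered record of create calls; one entry per call regardless of
    population size (en-bloc registration of non-local node metadata)."""

    entries: List[GidRange] = field(default_factory=list)

    @property
    def next_gid(self) -> int:
        return self.entries[-1].stop if self.entries else 0

    def model_of(self, gid: int) -> str:
        """Model id of ``gid`` by binary search over range entries."""
        lo, hi = 0, len(self.entries) - 1
        while lo <= hi:
            mid = (lo + hi) // 2
            entry = self.entries[mid]
            if gid < entry.first:
                hi = mid - 1
            elif gid >= entry.stop:
                lo = mid + 1
            else:
                return entry.model_id
        raise KeyError(f"gid {gid} not registered")

    def __len__(self) -> int:
        return len(self.entries)


def create_nodes(
    registry: ModelRegistry,
    model_id: str,
    count: int,
    layout: ParallelLayout,
    local_nodes: Optional[dict[int, list[int]]] = None,
) -> GidRange:
    """Append one contiguous gid block to ``registry``.

    Registry growth is one entry per call, independent of ``count``.  When
    ``local_nodes`` (a per-vp list of materialized local gids) is supplied,
    the local share of the new block is appended to each vp's list in
    ascending order — the per-node work is done only for local nodes.
    """
    if count < 1:
        raise EmptyPopulationError(f"cannot create {count} nodes")
    rng = GidRange(registry.next_gid, count, model_id)
    registry.entries.append(rng)
    if local_nodes is not None:
        for vp in range(layout.VP):
            local_nodes.setdefault(vp, []).extend(local_gids(vp, rng, layout))
    return rng
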