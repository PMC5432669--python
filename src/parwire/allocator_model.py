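"""Abstract allocator access-regime model.

Counts globally-guarded allocator interactions implied by per-VP
allocation/free event totals under two strategies:

* ``serialized`` — every alloc/free passes a global guard: guarded
  interactions = total events across VPs;
* ``thread_local_pool`` — each VP serves requests from a private pool and
  touches the guarded global pool only to fetch/return batches of R
  objects: per VP ``ceil(allocs/R)`` fetches plus ``ceil(frees/R)``
  returns.

Counts, not timings: the contention counts are the hardware-independent
surrogate for the observed multi-threaded construction scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

SERIALIZED = "serialized"
THREAD_LOCAL_POOL = "thread_local_pool"


@dataclass(frozen=True)
class AllocatorRegime:
    kind: str = SERIALIZED
    refill_size: int = 1

    def __post_init__(self) -> None:
        if self.kind not in (SERIALIZED, THREAD_LOCAL_POOL):
            raise ValueError(f"unknown allocator regime {self.kind!r}")
        if self.refill_size < 1:
            raise ValueError("refill_size must be >= 1")


@dataclass(frozen=True)
class ContentionSummary:
    guarded_interactions: int
    per_vp_events: Dict[int, int]
    regime: AllocatorRegime


def contention_summary(
    ledgers: Mapping[int, Tuple[int, int]],
    regime: AllocatorRegime,
) -> ContentionSummary:
    """Guarded-interaction count for per-VP ``(n_alloc, n_free)`` totals."""
    per_vp = {vp: n_alloc + n_free for vp, (n_alloc, n_free) in ledgers.items()}
    if regime.kind == SERIALIZED:
        guarded = sum(per_vp.values())
    else:
        R = regime.refill_size
        guarded = sum(
            math.ceil(n_alloc / R) + math.ceil(n_free / R)
            for n_alloc, n_free in ledgers.values()
        )
    return ContentionSummary(
        guarded_interactions=guarded, per_vp_events=per_vp, regime=regime
    )
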