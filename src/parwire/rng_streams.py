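"""Per-virtual-process random streams.

Construction results must be identical for a fixed number of virtual
processes regardless of how they are split into processes and threads.  All
randomness is therefore drawn from streams keyed by (master_seed, vp) only —
never by (M, T).

Streams are numpy ``Generator`` objects over Philox counter-based bit
generators, seeded through ``SeedSequence(master_seed, vp)``; the spawn-key
mixing of ``SeedSequence`` guarantees pairwise-independent, reproducible
streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

DEFAULT_SEED = 12345


class EmptySourceError(ValueError):
    """Uniform index requested over an empty population."""


def _make_stream(master_seed: int, vp: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(np.random.SeedSequence((master_seed, vp))))


@dataclass
class VpRngSuite:
    """One independent stream per virtual process.

    Streams are created lazily so that a dryrun of a single rank touches only
    that rank's streams; lazy creation cannot affect draw sequences because
    each stream depends only on ``(master_seed, vp)``.
    """

    master_seed: int
    VP: int
    _streams: Dict[int, np.random.Generator] = field(default_factory=dict, repr=False)

    def stream(self, vp: int) -> np.random.Generator:
        if not 0 <= vp < self.VP:
            raise ValueError(f"vp {vp} out of range for VP={self.VP}")
        st = self._streams.get(vp)
        if st is None:
            st = self._streams[vp] = _make_stream(self.master_seed, vp)
        return st


def make_suite(master_seed: int, layout_or_vp) -> VpRngSuite:
    """Build the per-vp stream suite for ``master_seed``.

    Accepts either a :class:`~parwire.topology.ParallelLayout` or a bare VP
    count — only the VP count enters the seeding.
    """
    vp_count = getattr(layout_or_vp, "VP", layout_or_vp)
    return VpRngSuite(master_seed=int(master_seed), VP=int(vp_count))


def draw_uniform_index(stream: np.random.Generator, n: int) -> int:
    """One uniform draw from ``[0, n)``."""
    if n < 1:
        raise EmptySourceError("cannot draw from an empty source population")
    return int(stream.integers(0, n))


def draw_uniform_indices(stream: np.random.Generator, n: int, size: int) -> np.ndarray:
    """``size`` uniform draws from ``[0, n)`` in one call.

    Equivalent to ``size`` successive :func:`draw_uniform_index` calls on the
    same stream (numpy's bounded-integer path is identical for scalar and
    vector requests), used by the wiring loops for speed.
    """
    if n < 1:
        raise EmptySourceError("cannot draw from an empty source population")
    return stream.integers(0, n, size=size)
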