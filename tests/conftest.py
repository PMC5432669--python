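import pytest

from parwire.benchmark_model import HpcBenchmarkSpec
from parwire.predictions import NetworkSpec
from parwire.topology import ParallelLayout


@pytest.fixture
def layout_2x2():
    return ParallelLayout(2, 2)


@pytest.fixture
def tiny_bench():
    """1000 neurons, in-degree 100 — builds in well under a second."""
    return HpcBenchmarkSpec(NetworkSpec(1000, 100, 0.8))


@pytest.fixture
def micro_bench():
    """100 neurons, in-degree 10 — for loops over many configurations."""
    return HpcBenchmarkSpec(NetworkSpec(100, 10, 0.8))


def factorizations(vp):
    """All (M, T) with M*T == vp."""
    return [(m, vp // m) for m in range(1, vp + 1) if vp % m == 0]
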