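import pytest

from msicall import PanelConfig, Peak, Trace
from msicall.trace_io import NORMAL, TUMOUR


@pytest.fixture
def config() -> PanelConfig:
    return PanelConfig()


def make_trace(sizes_signals, marker="BAT-25", role=TUMOUR, sample="s1") -> Trace:
    return Trace(sample, marker, role, tuple(Peak(s, r) for s, r in sizes_signals))


@pytest.fixture
def trace_factory():
    return make_trace


@pytest.fixture
def normal_factory():
    def _make(sizes_signals, marker="BAT-25", sample="s1"):
        return make_trace(sizes_signals, marker=marker, role=NORMAL, sample=sample)

    return _make
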