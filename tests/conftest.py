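import pytest

from anisobind import ProbeParams


@pytest.fixture
def probe() -> ProbeParams:
    """The fluorescein-maytansinol tracer's endpoint parameters."""
    return ProbeParams(rf=0.016, rb=0.245, R=3.1)
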