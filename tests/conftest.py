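import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracles.py

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def water_bath():
    from oocyteswell import hypotonic_water_bath

    return hypotonic_water_bath()


@pytest.fixture
def urea_bath():
    from oocyteswell import isotonic_solute_bath

    return isotonic_solute_bath("urea")
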