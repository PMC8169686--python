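import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the dash_oracle module

from fickflow.circuit_simulator import CircuitConfig, records_from_protocol, solve_steady_state


@pytest.fixture(scope="session")
def baseline_config():
    """The bench's baseline operating point: 2000/500 ml/min split."""
    return CircuitConfig()


@pytest.fixture(scope="session")
def baseline_state(baseline_config):
    return solve_steady_state(baseline_config)


@pytest.fixture(scope="session")
def records_1a():
    """Noise-free step-1a protocol records (V/Q = 1 at the ECMO)."""
    return records_from_protocol("1a")


@pytest.fixture(scope="session")
def records_1b():
    """Noise-free step-1b records (ECMO sweep fixed at 1500 ml/min)."""
    return records_from_protocol("1b")
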