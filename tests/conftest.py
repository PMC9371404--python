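"""Shared fixtures: the expensive calibrated scenario runs are computed once
per session and reused by the unit and acceptance tests."""

import numpy as np
import pytest

from assoclearn.behavior import simulate_and_classify
from assoclearn.circuits import FDParams, FernandoParams
from assoclearn.protocols import (
    fd_conditioning_protocol,
    fd_no_conditioning_protocol,
    fernando_conditioning_protocol,
)


@pytest.fixture(scope="session")
def fernando_default_run():
    """Hebbian circuit, table defaults (a=4, b=2), calibrated ten-event protocol."""
    return simulate_and_classify("fernando")


@pytest.fixture(scope="session")
def fd_default_run():
    """Dissociation circuit, table defaults (a=2), calibrated eight-event protocol."""
    return simulate_and_classify("fd")


@pytest.fixture(scope="session")
def adjusted_default_run():
    return simulate_and_classify("adjusted_fd")


@pytest.fixture(scope="session")
def fd_no_conditioning_run():
    return simulate_and_classify("fd", protocol=fd_no_conditioning_protocol())


@pytest.fixture
def rng():
    return np.random.default_rng(20220807)
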