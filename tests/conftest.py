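import math

import numpy as np
import pytest
from hypothesis import settings

from pulsecomp import CircuitParams, CoilParams

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coil() -> CoilParams:
    """The reference bench coil: 1 MHz, Q = 49.83."""
    return CoilParams(f_r=1e6, q=49.83)


@pytest.fixture(scope="session")
def circuit() -> CircuitParams:
    """Series RLC tuned near 1 MHz with Q ~ 49.9."""
    return CircuitParams(L=10e-6, R=1.26, C=2.533e-9)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def circuit_with_q(q: float) -> CircuitParams:
    """Series RLC at ~1 MHz with the requested quality factor."""
    L, C = 10e-6, 2.533e-9
    omega = 1.0 / math.sqrt(L * C)
    return CircuitParams(L=L, R=omega * L / q, C=C)
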