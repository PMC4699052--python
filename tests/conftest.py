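"""Shared fixtures: toy parameter sets and engines (session-scoped, since
key generation and slot-layout construction dominate test runtime)."""

import numpy as np
import pytest

from hegenome.engines import (
    BGVEngine,
    PlainEngine,
    YASHECoeffEngine,
    YASHESlotEngine,
)
from hegenome.profiles import toy_profile


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240715)


@pytest.fixture(scope="session")
def bgv_t1_engine():
    return BGVEngine(toy_profile("bgv", "task1"), np.random.default_rng(11))


@pytest.fixture(scope="session")
def bgv_t2_engine():
    return BGVEngine(toy_profile("bgv", "task2"), np.random.default_rng(12))


@pytest.fixture(scope="session")
def yashe_t1_engine():
    return YASHECoeffEngine(toy_profile("yashe", "task1"),
                            np.random.default_rng(13))


@pytest.fixture(scope="session")
def yashe_t2_engine():
    return YASHESlotEngine(toy_profile("yashe", "task2"),
                           np.random.default_rng(14))


@pytest.fixture()
def plain_bin():
    return PlainEngine(2, 8)


@pytest.fixture()
def plain_arith():
    return PlainEngine(127, 32)
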