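import numpy as np
import pytest

from ocdim.datasets import (
    AffectedFlags,
    DomainMap,
    ItemResponseMatrix,
    SeverityMatrix,
)
from ocdim.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-person default-structure cohort shared across read-only tests."""
    cfg = SimConfig(n_persons=400, seed=42)
    params, resp, sev, flags = simulate_cohort(cfg)
    return params, resp, sev, flags


@pytest.fixture()
def toy_resp():
    values = np.array(
        [
            [1.0, 0.0, 1.0],
            [0.0, 0.0, 0.0],
            [1.0, 1.0, np.nan],
            [0.0, 1.0, 0.0],
        ]
    )
    return ItemResponseMatrix(["p1", "p2", "p3", "p4"], ["i1", "i2", "i3"], values)


@pytest.fixture()
def toy_map():
    return DomainMap(
        {"i1": "doubt_checking", "i2": "doubt_checking", "i3": "taboo"},
        strict=False,
    )


@pytest.fixture()
def toy_severity():
    values = np.full((4, 10), np.nan)
    values[0] = np.arange(10) % 5
    values[3] = 1.0
    return SeverityMatrix(
        ["p1", "p2", "p3", "p4"], [f"s{k}" for k in range(10)], values
    )


@pytest.fixture()
def toy_flags():
    return AffectedFlags({"p1": True, "p2": False, "p3": True, "p4": False})
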