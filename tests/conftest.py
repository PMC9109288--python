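"""Shared fixtures: a desk-scale end-to-end replica run (computed once per
session) plus small helper configs."""

import numpy as np
import pytest
from hypothesis import settings

from pleiocost import pipeline

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def replica_report():
    """Full desk-scale replica (simulate + analyze + headline checks) at the
    default seed; shared across tests because it is the expensive object."""
    return pipeline.replica(seed=0)


@pytest.fixture(scope="session")
def replica_result(replica_report):
    return replica_report["_result"]


@pytest.fixture(scope="session")
def replica_config():
    return pipeline.replica_config(seed=0)


@pytest.fixture(scope="session")
def control_reports():
    """Replica variants that switch the pleiotropic cost off (c=0) or make it
    fully dominant (h_c=1); only the diverged pair is simulated."""
    return {
        "no_cost": pipeline.replica(seed=0, cost=0.0, diverged_only=True),
        "dominant_cost": pipeline.replica(seed=0, cost_dominance=1.0, diverged_only=True),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
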