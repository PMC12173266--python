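"""Shared fixtures and deterministic hypothesis settings."""

import pytest
from hypothesis import HealthCheck, settings

from medmr import LDBlocks, SimScenario, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_SCENARIO = SimScenario(
    n_snps=60,
    n_exposure=2500,
    n_mediator=2500,
    n_outcome=6000,
    n_instruments_x=12,
    n_instruments_m=12,
    n_instruments_y=8,
    ld_blocks=LDBlocks(block_size=3, r=0.8),
    seed=7,
)


@pytest.fixture(scope="session")
def sim_world():
    """One individual-level synthetic world shared across tests (read-only)."""
    return simulate(SMALL_SCENARIO)
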