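"""Shared fixtures.

The expensive driver simulations are session-scoped so every test file reuses
the same trajectories instead of re-integrating the model.
"""
from __future__ import annotations

import numpy as np
import pytest

from cortsync import (
    CortisolParameters,
    SyncConfig,
    densify,
    run_synchronization,
    simulate_driver,
)


@pytest.fixture(scope="session")
def nominal_params() -> CortisolParameters:
    return CortisolParameters.nominal()


@pytest.fixture(scope="session")
def driver_one_cycle(nominal_params):
    """Noiseless nominal driver, 1-min sampling, one circadian cycle."""
    return simulate_driver(nominal_params, 1)


@pytest.fixture(scope="session")
def driver_two_cycles(nominal_params):
    """Noiseless nominal driver, 1-min sampling, two circadian cycles."""
    return simulate_driver(nominal_params, 2)


@pytest.fixture(scope="session")
def sparse_densified(nominal_params):
    """45-min sampled six-cycle driver densified to a 5-min grid."""
    sparse = simulate_driver(nominal_params, 6, sampling_interval=45.0)
    return densify(sparse, 5.0)


@pytest.fixture(scope="session")
def sparse_sync(sparse_densified):
    """Observer run on the sparse noiseless six-cycle scenario."""
    cfg = SyncConfig(total_cycles=6, burn_in_cycles=5, extract_window="full")
    return run_synchronization(sparse_densified, cfg)


@pytest.fixture(scope="session")
def dense_clean_sync(driver_two_cycles):
    """Observer run on the noiseless dense two-cycle scenario."""
    cfg = SyncConfig(total_cycles=2, burn_in_cycles=1, extract_window="last_cycle")
    return run_synchronization(driver_two_cycles, cfg)
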