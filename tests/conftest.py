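"""Shared fixtures: the expensive steady-state run is computed once."""

import numpy as np
import pytest

from paracortex.engine import SimulationConfig, run_simulation


@pytest.fixture(scope="session")
def steady_run_10k():
    """Six simulated days of a 10k-cell blob at T_res = 12 h, no chemotaxis.

    Calibrated automatic exit portals and constant influx N0/T_res; used by
    the residence-time, conservation and egress-flux checks.
    """
    config = SimulationConfig(
        n0=10_000,
        t_res_min=720.0,
        p_e=0.02,
        duration_days=6.0,
        seed=11,
        record_every=20,
    )
    return run_simulation(config)


@pytest.fixture(scope="session")
def small_steady_run():
    """A 2k-cell steady-state run for cheap structural checks."""
    config = SimulationConfig(
        n0=2000, duration_days=1.0, seed=3, record_every=8
    )
    return run_simulation(config)
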