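import logging

import numpy as np
import pytest

from pphrv import (FitConfig, ParameterTrajectory, build_basis,
                   fit_trajectory, simulate_renewal)
from pphrv.rr_io import EventSeries

logging.getLogger("pphrv").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def basis():
    return build_basis(0.2, 3)


@pytest.fixture(scope="session")
def renewal_events():
    """10-minute constant-parameter (renewal) simulation, mean 0.8 s."""
    return simulate_renewal(0.8, 1500.0, 600.0, seed=2)


@pytest.fixture(scope="session")
def fitted_trajectory(renewal_events):
    return fit_trajectory(renewal_events, FitConfig(step_delta=0.1))


@pytest.fixture(scope="session")
def modulated_events():
    """Respiratory-modulated renewal series (entropy / complexity fixture)."""
    return simulate_renewal(lambda t: 0.8 + 0.05 * np.sin(2 * np.pi * 0.1 * t),
                            1500.0, 200.0, seed=11)


@pytest.fixture(scope="session")
def modulated_trajectory(modulated_events):
    return fit_trajectory(modulated_events, FitConfig(step_delta=0.5))


@pytest.fixture
def toy_events():
    return EventSeries.from_rr_intervals(np.array([0.80, 0.85, 0.79]),
                                         t_end=3.0)
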