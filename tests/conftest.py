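import numpy as np
import pytest

import usospa as u


@pytest.fixture(scope="session")
def baseline():
    return u.preset("baseline_sec3")


@pytest.fixture(scope="session")
def uniform():
    return u.preset("uniform_sec4")


@pytest.fixture(scope="session")
def baseline_traj(baseline):
    """One full-model baseline integration shared across tests."""
    return u.integrate(baseline.params, baseline.initial)


def make_trajectory(values, dt=1.0, compartment="P", params=None):
    """Hand-built trajectory whose chosen compartment follows `values`.

    The remaining mass is parked in S so state invariants hold; useful for
    exercising metrics on exactly known curves.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    cols = {"S": None, "O": 0.0, "P": 0.0, "U": 0.0}
    cols[compartment] = values
    states = np.zeros((n, 4))
    states[:, 2] = cols["P"]
    states[:, 1] = cols["O"]
    states[:, 3] = cols["U"]
    states[:, 0] = 1.0 - states[:, 1:].sum(axis=1)
    return u.Trajectory(
        times=np.arange(n) * dt,
        states=states,
        params=params or u.ModelParameters(),
        meta={"method": "synthetic", "dt": dt, "t_end": (n - 1) * dt,
              "variant": "full"},
    )
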