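import numpy as np
import pytest

from ephapse import FHNParams, GridSpec, impulse_protocol, simulate_discrete


@pytest.fixture(scope="session")
def fhn_default():
    return FHNParams()


@pytest.fixture(scope="session")
def small_grid():
    """6 axons x 40 z-nodes, 200 steps: the dense-oracle comparison size."""
    return GridSpec(z_extent=20.0, t_end=10.0, n_lateral=6, dz=0.5, dt=0.05)


@pytest.fixture(scope="session")
def small_discrete_run(fhn_default, small_grid):
    protocol = impulse_protocol([(3, 0.0)])
    return simulate_discrete(small_grid, 0.8, fhn_default, protocol,
                             store_w=True)


@pytest.fixture(scope="session")
def single_impulse_run(fhn_default):
    """One axon stimulated on a domain long enough for clean propagation."""
    grid = GridSpec(z_extent=160.0, t_end=120.0, n_lateral=5, dz=0.5)
    protocol = impulse_protocol([(3, 0.0)])
    return simulate_discrete(grid, 0.8, fhn_default, protocol)


def rest_state_array(fhn, shape):
    from ephapse import resting_state

    rest = resting_state(fhn)
    return (np.full(shape, rest.v_star), np.full(shape, rest.w_star))
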