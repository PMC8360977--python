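import numpy as np
import pytest

import neulag as nl


@pytest.fixture(scope="session")
def three_node():
    """Default symmetric 3-node network (original variant)."""
    return nl.make_three_node_network()


@pytest.fixture(scope="session")
def three_node_modified():
    return nl.make_three_node_network(variant="modified")


@pytest.fixture(scope="session")
def quiet_noise():
    return nl.NoiseSpec()


@pytest.fixture(scope="session")
def onshell_fine():
    """Non-dissipative modified trajectory on a fine grid (dt = 0.002), the
    regime where central-difference mechanics diagnostics are accurate."""
    spec = nl.make_three_node_network(variant="modified").with_(non_dissipative=True)
    z0 = np.array([1.0, 0.5j, -0.2])
    traj = nl.simulate_modified(spec, z0, None, nl.NoiseSpec(), T=1025, dt=0.002)
    return traj, spec


@pytest.fixture(scope="session")
def ten_seed_experiments():
    """Shared 2x2 inversion grids for seeds 0..9 (reused by the acceptance
    tests for identifiability and parameter recovery)."""
    return {seed: nl.identifiability_experiment(seed=seed) for seed in range(10)}
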