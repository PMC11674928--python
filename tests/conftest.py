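import numpy as np
import pytest

import dmfsim as d


@pytest.fixture(scope="session")
def params():
    return d.DMFParameters()


@pytest.fixture(scope="session")
def hemo():
    return d.HemodynamicParameters()


@pytest.fixture(scope="session")
def box_coords():
    # 30 mm box: pairwise distances where the lambda=0.18/mm kernel is
    # informative (neither identity nor flat)
    return d.make_coordinates(20, geometry="box", scale=30.0, seed=2)


@pytest.fixture(scope="session")
def tiny_connectome(box_coords):
    """20-node modular fixture at the calibrated strength scale.

    Mean strength 0.5 keeps the linear FIC rule stable up to G ~ 2 at
    alpha = 0.75, mirroring the stability range reported for empirical
    connectomes; the modular structure gives the switching FC dynamics
    the FCD objective needs.
    """
    return d.make_connectome(
        d.ConnectomeSpec(n_regions=20, model="modular",
                         target_mean_strength=0.5, seed=1),
        coordinates=box_coords)


@pytest.fixture(scope="session")
def single_node_run(params, hemo):
    """110-s single uncoupled region, 10 s discarded (shared across tests)."""
    conn = d.Connectome(np.zeros((1, 1)))
    cfg = d.IntegrationConfig(duration=110.0, seed=42)
    return d.run_simulation(params, hemo, conn,
                            d.CouplingConfig(G=0.0, J=[1.0]), cfg)
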