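import numpy as np
import pytest

from lipopore import synth


@pytest.fixture(scope="session")
def open_pore_traj():
    cfg = synth.MembraneTrajectoryConfig(seed=11, pore="open", n_frames=30)
    return synth.gen_membrane_trajectory(cfg)


@pytest.fixture(scope="session")
def intact_traj():
    cfg = synth.MembraneTrajectoryConfig(seed=11, pore="none", n_frames=30)
    return synth.gen_membrane_trajectory(cfg)


@pytest.fixture(scope="session")
def umbrella_cosine():
    """15-window umbrella dataset on the 20 kJ/mol cosine landscape."""
    G = synth.cosine_landscape(20.0)
    windows, truth = synth.gen_umbrella_dataset(
        G, np.linspace(0.0, 1.0, 15), n_per_window=20_000, seed=7
    )
    return windows, truth, G
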