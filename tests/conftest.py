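import numpy as np
import pytest

import flexcat as fc


@pytest.fixture(scope="session")
def cfg():
    return fc.TaskConfig()


@pytest.fixture(scope="session")
def log_cfg():
    """Exactly log-spaced 7-SF set spanning one decade (0.03 to 0.3)."""
    sfs = tuple(0.03 * 10 ** (i / 6) for i in range(7))
    return fc.TaskConfig(sf_values=sfs)


@pytest.fixture(scope="session")
def m4_dataset():
    """Closed-loop simulation of the reduced model at the study medians,
    at the study scale (50 blocks per type)."""
    return fc.simulate_agent("m4", fc.M4_MEDIANS,
                             fc.SimConfig(n_blocks_per_type=50, seed=11))


@pytest.fixture(scope="session")
def m4_small():
    """Smaller m4 simulation for fitting tests (20 blocks per type)."""
    return fc.simulate_agent("m4", fc.M4_MEDIANS,
                             fc.SimConfig(n_blocks_per_type=20, seed=7))
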