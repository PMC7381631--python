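"""Shared fixtures: small-grid system functions reused across the suite.

System-function simulation is the expensive step, so noiseless SFs on
reduced grids are session-scoped; they use the default scanner's drive and
selection fields with a coarser time sampling of the Lissajous period.
"""

import numpy as np
import pytest

from aaampi.physics import FieldSequence, ParticleModel
from aaampi.synth import VoxelGrid, simulate_system_function


@pytest.fixture(scope="session")
def seq():
    return FieldSequence().downsampled(13464)


@pytest.fixture(scope="session")
def model_immobilized():
    return ParticleModel.ferucarbotran_immobilized()


@pytest.fixture(scope="session")
def model_fluid():
    return ParticleModel.ferucarbotran_fluid()


@pytest.fixture(scope="session")
def grid9():
    return VoxelGrid((9, 9, 5), (9.0, 9.0, 5.0))


@pytest.fixture(scope="session")
def grid13():
    return VoxelGrid((13, 13, 9), (13.0, 13.0, 9.0))


@pytest.fixture(scope="session")
def sf_im9(grid9, seq, model_immobilized):
    return simulate_system_function(grid9, seq, model_immobilized, noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def sf_fl9(grid9, seq, model_fluid):
    return simulate_system_function(grid9, seq, model_fluid, noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def sf13(grid13, seq, model_immobilized):
    return simulate_system_function(grid13, seq, model_immobilized, noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200723)
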