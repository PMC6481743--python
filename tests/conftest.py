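import numpy as np
import pytest
from hypothesis import settings

import aortaflow as af

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tube():
    """Default-resolution straight tube (R = 1 cm) with exact area pi R^2 = 3.1416e-4 m2."""
    return af.make_straight_tube_mesh(0.01, 0.1)


@pytest.fixture(scope="session")
def fluid():
    return af.FluidProperties()  # blood: mu = 4e-3 Pa s, rho = 1060 kg/m3


@pytest.fixture(scope="session")
def waveform():
    return af.aortic_waveform(n_samples=40)


def constant_waveform(q0: float, n: int = 20, period: float = 1.0) -> af.FlowWaveform:
    t = np.arange(n) * period / n
    return af.FlowWaveform(times=t, q=np.full(n, q0), period=period,
                           systolic_markers=[0.07, 0.14, 0.21, 0.28])


@pytest.fixture(scope="session")
def uniform_field(tube):
    """Spatially and temporally uniform velocity (0.3, 0, 0.4) m/s."""
    times = np.arange(4) * 0.25
    vel = np.tile(np.array([0.3, 0.0, 0.4]), (4, tube.n_nodes, 1))
    return af.TimeVaryingField(mesh=tube, times=times, velocity=vel, period=1.0)
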