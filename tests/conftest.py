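import numpy as np
import pytest

from isnplast.core import NO_NOISE, NetworkParams, WeightSet
from isnplast.plasticity import LearningRates, SetPoints


@pytest.fixture(scope="session")
def params():
    return NetworkParams()


@pytest.fixture(scope="session")
def setpoints():
    return SetPoints()


@pytest.fixture(scope="session")
def isn_weights():
    """Weight set whose self-sustained fixed point sits at (5, 10) Hz."""
    return WeightSet(5.0, 1.52, 10.0, 2.25)


@pytest.fixture(scope="session")
def balanced_weights():
    """Printed weight set generating self-sustained activity at (5, 14) Hz."""
    return WeightSet(5.0, 1.09, 10.0, 1.54)


@pytest.fixture(scope="session")
def weak_weights():
    """Developmental initialization too weak for self-sustained activity."""
    return WeightSet(2.1, 3.0, 4.0, 2.0)


@pytest.fixture(scope="session")
def no_noise():
    return NO_NOISE


def active_branch_solve(params, w, ext_E=0.0, ext_I=0.0):
    """Independent oracle: direct 2x2 linear solve of the fully active branch.

    E = g_E (W_EE E - W_EI I + ext_E - theta_E)
    I = g_I (W_IE E - W_II I + ext_I - theta_I)
    """
    gE, gI = params.g_E, params.g_I
    A = np.array([[1 - gE * w.W_EE, gE * w.W_EI],
                  [-gI * w.W_IE, 1 + gI * w.W_II]])
    b = np.array([gE * (ext_E - params.theta_E), gI * (ext_I - params.theta_I)])
    return np.linalg.solve(A, b)
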