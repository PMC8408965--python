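import numpy as np
import pytest

from selexmotif.motif_model import Pwm
from selexmotif.selex_sim import planted_pwm


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform_pwm():
    return Pwm(name="uniform", matrix=np.full((6, 4), 0.25))


def random_pwm(rng, width, name="rand"):
    mat = rng.dirichlet(np.ones(4), size=width)
    return Pwm(name=name, matrix=mat)


@pytest.fixture
def sharp_pwm():
    return planted_pwm("ACGTCAGT", certainty=0.94, name="sharp")
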