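import numpy as np
import pytest

from navlti.markov import KineticScheme, RateConstant
from navlti.models import make_lti_model, make_non_lti_model


@pytest.fixture(scope="session")
def lti_model():
    return make_lti_model()


@pytest.fixture(scope="session")
def lti_model_set2():
    return make_lti_model(os_set="set2")


@pytest.fixture(scope="session")
def non_lti_model():
    return make_non_lti_model()


@pytest.fixture()
def two_state():
    """Two-state scheme A <-> B with voltage-independent rates a=0.4, b=0.1."""
    return KineticScheme(
        ["A", "B"],
        {"A": False, "B": True},
        [("A", "B", RateConstant(0.4)), ("B", "A", RateConstant(0.1))],
    )


def random_scheme(rng: np.random.Generator, n_states: int) -> KineticScheme:
    """Random connected reversible chain scheme with mild voltage dependence."""
    names = [f"S{i}" for i in range(n_states)]
    transitions = []
    for i in range(n_states - 1):
        k0f, k0b = rng.uniform(0.05, 2.0, size=2)
        k1f, k1b = rng.uniform(-0.05, 0.05, size=2)
        transitions.append((names[i], names[i + 1], RateConstant(k0f, k1f)))
        transitions.append((names[i + 1], names[i], RateConstant(k0b, k1b)))
    return KineticScheme(names, {names[-1]: True}, transitions)
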