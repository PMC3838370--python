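import numpy as np
import pytest

from fishersum import ScenarioSpec, SimulationDesign, TwoGroupVector, build_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def random_vector(rng):
    """A generic non-degenerate two-group vector."""
    return TwoGroupVector(rng.normal(size=25), rng.normal(size=30))


@pytest.fixture(scope="session")
def small_matrix():
    """A small scenario-I benchmark matrix shared by read-only tests."""
    design = SimulationDesign(
        n=20, spec=ScenarioSpec("I", 3.0, 0.2), counts=(25, 25, 50), seed=424242
    )
    return build_matrix(design)
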