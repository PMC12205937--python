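import pytest

from coyield import SolveOptions, ThermoConfig
from coyield.fixtures import ToySpec, toy_model, toy_pair


@pytest.fixture(scope="session")
def config():
    return ThermoConfig()


@pytest.fixture()
def chain2():
    """Two-reaction chain with favorable thermodynamics throughout."""
    return toy_model(ToySpec(dG0_list=(-10.0, -10.0)))


@pytest.fixture()
def chain1():
    return toy_model(ToySpec(n_chain=1, dG0_list=(-10.0,)))


@pytest.fixture()
def pair_model():
    """Chain with an embedded reversible pair (both directions listed)."""
    return toy_model(ToySpec(dG0_list=(-10.0, -10.0), include_reverse_pair=True))


@pytest.fixture()
def consortium():
    """Identifiable upstream/downstream pair: the downstream uptake bound
    is small enough that upstream-rich ratios leave it demand-limited."""
    return toy_pair(ToySpec(), ToySpec(uptake_bound=0.5))


@pytest.fixture(scope="session")
def thermo_options():
    return SolveOptions(use_thermo=True)
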