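import pytest

from retroepi import synthetic_data as sd


@pytest.fixture(scope="session")
def sim():
    """Default 2 Mb synthetic genome with five TE families."""
    return sd.simulate_genome(sd.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def by_class(sim):
    classes = {}
    for c in sim.copies:
        classes.setdefault(c.te_class, []).append(c)
    return classes


@pytest.fixture(scope="session")
def chip(sim):
    """ChIP simulation binding the young L1 family and the LTR enhancers."""
    return sd.simulate_chip(sim, {"L1Md_T": 0.8, "RLTR13D6": 0.5}, seed=2)
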