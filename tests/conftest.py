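import pytest

from coldscan import synthdata


@pytest.fixture(scope="session")
def sweep_sim():
    """Near-fixation hard sweep (f = 0.9) on the default 2 Mb contig."""
    return synthdata.simulate(synthdata.SimConfig(seed=11, sweep_on=True))


@pytest.fixture(scope="session")
def sweep_sim_complete():
    """Completed hard sweep (f = 1.0)."""
    return synthdata.simulate(
        synthdata.SimConfig(seed=11, sweep_on=True, sweep_fraction=1.0))


@pytest.fixture(scope="session")
def neutral_sim():
    return synthdata.simulate(synthdata.SimConfig(seed=11))
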