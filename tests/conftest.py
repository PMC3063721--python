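import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def poisson_pair(rng):
    """Two independent 18-Hz Poisson neurons, 20 s at 1-ms bins."""
    import ppgranger as pg

    n_bins = 20_000
    counts = (rng.random((2, n_bins)) < 0.018).astype(np.int8)
    return pg.BinnedEnsemble(counts, delta=0.001)


@pytest.fixture(scope="session")
def fig1_run():
    """One 100k-bin realisation of the nine-neuron benchmark, pre-binned."""
    import ppgranger as pg

    spec = pg.preset_fig1()
    ens = pg.simulate(spec, 100_000, seed=11)
    return spec, ens, pg.bin_spikes(ens)
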