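import numpy as np
import pytest

from csdgp import ElectrodeGeometry, GPCSDParams, LFPTrials


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def geom3():
    """Tiny 3-electrode laminar geometry for dense oracles."""
    return ElectrodeGeometry(np.array([0.0, 120.0, 300.0]))


@pytest.fixture
def geom24():
    """Benchmark-sized laminar probe: 24 electrodes spanning 0-2400 um."""
    return ElectrodeGeometry(np.linspace(0.0, 2400.0, 24))


@pytest.fixture
def toy_params():
    return GPCSDParams(
        R=100.0, ell_s=150.0, ell_t1=2.0, ell_t2=5.0,
        var1=0.5, var2=0.8, noise_var=0.1,
    )


@pytest.fixture
def toy_lfp(rng, geom3):
    times = np.arange(4.0)
    data = rng.standard_normal((2, 3, 4))
    return LFPTrials(data, times, geom3, 1000.0)
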