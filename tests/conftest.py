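import numpy as np
import pytest

from hydrosub.ctrw import WaitingTimeModel
from hydrosub.synthetic import SpectraSpec, gen_cole_cole_spectra


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def exponential_model():
    return WaitingTimeModel(kind="exponential", mean=1.0)


@pytest.fixture
def pareto_half_model():
    return WaitingTimeModel(kind="pareto", tail_exponent=0.5, t_min=0.01)


@pytest.fixture
def noiseless_grid():
    """Clean susceptibility grid: 5 q-slices, tau(q) = 10 q^-2.2, alpha 0.2."""
    q = np.array([0.7, 0.9, 1.1, 1.3, 1.5])
    taus = 10.0 * q**-2.2
    spec = SpectraSpec(
        q_values=q,
        taus=taus,
        alphas=np.full(5, 0.2),
        chi0s=np.ones(5),
        frequencies=np.geomspace(1e-5, 10.0, 200),
        noise_level=0.0,
    )
    return gen_cole_cole_spectra(spec), spec
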