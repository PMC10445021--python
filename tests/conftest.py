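import numpy as np
import pytest

from trpgating import DwellLaw, GatingScheme, ThermoParams


@pytest.fixture
def markov_scheme() -> GatingScheme:
    """Two-state Markov limit with opening rate 2/s and closing rate 1/s."""
    return GatingScheme.two_state_markov(2.0, 1.0)


@pytest.fixture
def gamma_scheme() -> GatingScheme:
    """Two-state gamma dwells (shape 2) with means 0.5 s (C) and 0.2 s (O)."""
    return GatingScheme.two_state(DwellLaw.gamma(2.0, 0.25), DwellLaw.gamma(2.0, 0.1))


@pytest.fixture
def asymmetric_thermo() -> ThermoParams:
    """Opening barrier above the closing barrier: opening is the slow step."""
    return ThermoParams(dG_barrier_o=60e3, dG_barrier_c=45e3, nu0=1e9)


@pytest.fixture
def grid() -> np.ndarray:
    return np.concatenate(([0.0], np.geomspace(0.01, 3.0, 25)))
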