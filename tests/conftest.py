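import numpy as np
import pytest

from nanopearl import PearlChainSpec, gen_pearl_profile

#: Table-style cohort means (nsv_length, nsv_width, connector_length,
#: connector_width) in nm used across the tests.
DISSOCIATED = (600.0, 311.0, 552.0, 127.0)
ORGANOTYPIC = (326.0, 177.0, 252.0, 52.0)
ACUTE = (357.0, 204.0, 380.0, 58.0)


@pytest.fixture(scope="session")
def dissociated_profile():
    """Noiseless ten-pearl chain at the dissociated-culture means."""
    return gen_pearl_profile(PearlChainSpec(*DISSOCIATED, n_periods=10, seed=1))


@pytest.fixture(scope="session")
def cosine_profile():
    """Pure cosine chain with analytic inflection points at lambda/4 + k lambda/2."""
    from nanopearl import RadiusProfile

    lam = 800.0
    x = np.arange(0.0, 8000.0, 5.0)
    r = 100.0 + 30.0 * np.cos(2 * np.pi * x / lam)
    return RadiusProfile(x, r), lam
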