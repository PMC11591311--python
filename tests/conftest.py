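import numpy as np
import pytest

import sociorhythm as sr
from sociorhythm.synthdata import SimConfig


@pytest.fixture(scope="session")
def small_run():
    """One small but full pipeline run shared across tests."""
    cfg = sr.RunConfig(sim=SimConfig(n_employees=60, n_orgs=2, n_days=2,
                                     rng_seed=7))
    return sr.run(cfg)


@pytest.fixture(scope="session")
def coupled_run():
    """A run with a strong planted partner coupling, for sign checks."""
    cfg = sr.RunConfig(sim=SimConfig(n_employees=150, n_orgs=3, n_days=4,
                                     coupling_pe_partner_ds=-0.3, rng_seed=11))
    return sr.run(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
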