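import numpy as np
import pytest

import syndemap as sm


@pytest.fixture(scope="session")
def small_geo():
    return sm.make_geography(30, 10, 3, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_geo):
    cfg = sm.TruthConfig(n_covariates=2, beta=np.tile([0.3, -0.2], (2, 1)),
                         delta=np.array([1.4, 1.0 / 1.4]),
                         sigma2_phi=0.3, sigma2_psi=0.1, base_rate=2e-3)
    panel, truth = sm.simulate_panel(small_geo, 2, 6, cfg, seed=12)
    return panel, truth


@pytest.fixture(scope="session")
def censored_small_panel(small_panel):
    panel, truth = small_panel
    return sm.apply_confidentiality_censoring(panel), truth


@pytest.fixture(scope="session")
def quick_fit(censored_small_panel, small_geo):
    """A small but real MCMC fit shared across tests."""
    panel, truth = censored_small_panel
    spec = sm.ModelSpec(n_iter=600, burn_in=250, thinning=1, seed=13)
    return sm.run_mcmc(panel, None, small_geo, spec)
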