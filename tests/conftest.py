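"""Shared fixtures: the default network and cached reference simulations."""

import numpy as np
import pytest

import chronotox as ct


@pytest.fixture(scope="session")
def system():
    return ct.build_network()


@pytest.fixture(scope="session")
def wt_params(system):
    return system.default_parameters


@pytest.fixture(scope="session")
def wt_cycle(system, wt_params):
    """Post-transient free-running trajectory and period."""
    return ct.limit_cycle(system, wt_params, window=24 * 7)


@pytest.fixture(scope="session")
def pkpd_params():
    return ct.default_pkpd_parameters()


@pytest.fixture(scope="session")
def drug_proteins(wt_cycle, pkpd_params):
    """Rescaled drug-protein courses on the free-running limit cycle."""
    traj, _ = wt_cycle
    prot = ct.translate_proteins(traj, pkpd_params)
    return ct.pkpd.rescaled_drug_proteins(prot, pkpd_params)


@pytest.fixture(scope="session")
def model_dataset(system, wt_params):
    """Noiseless model-generated expression at a study-like sampling grid."""
    times = np.arange(0.0, 45.1, 3.0)
    return ct.fitting.model_generated_dataset(system, wt_params, times)


@pytest.fixture(scope="session")
def synthetic_spec():
    return ct.default_synthetic_spec(seed=42)
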