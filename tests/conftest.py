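import numpy as np
import pytest

from spastikit import (MechParams, ProtocolConfig, SweProfileParams,
                       default_cohort_params, simulate_cohort, simulate_subject)

ZERO_PARAMS = MechParams(m_eff=0.0, m_platform=0.0, r_eff=0.08,
                         k_lin=0.0, k_exp=0.0, k_rate=0.07, theta0=-20.0,
                         b=0.0, v_th=50.0, tau=0.05, A_N=0.0, rise=0.1,
                         sigma=0.0, offset=0.0)

QUIET_PARAMS = MechParams(sigma=0.0)  # paretic-like defaults, no sensor noise


@pytest.fixture(scope="session")
def cfg():
    return ProtocolConfig()


@pytest.fixture(scope="session")
def quiet_subject(cfg):
    """One noiseless subject with paretic-like mechanics on both sides."""
    params = {
        "paretic": (QUIET_PARAMS, SweProfileParams(mu0=12.0, c=0.02, sigma_mu=0.0)),
        "non_paretic": (MechParams(sigma=0.0, k_lin=0.024, k_exp=0.02,
                                   k_rate=0.064, b=0.0008, A_N=1.9),
                        SweProfileParams(mu0=8.0, c=0.008, sigma_mu=0.0)),
    }
    return simulate_subject("QS", params, cfg, seed=7)


@pytest.fixture(scope="session")
def small_cohort(cfg):
    """Default-calibrated cohort at reduced size, shared across tests."""
    return simulate_cohort(default_cohort_params(n_subjects=6), seed=11, cfg=cfg)
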