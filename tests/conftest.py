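import numpy as np
import pytest

import dpphkin as dk

GALLIC_K1 = 1.13e3
GALLIC_K2 = 145.0
GALLIC_AOH0 = 29e-6
SINAPIC_K1 = 5.67e3
SINAPIC_AOH0 = 18e-6
DPPH0 = 100e-6
AOH_KNOWN = 10e-6


@pytest.fixture(scope="session")
def assay_ctx():
    return dk.AssayContext(dpph0_nominal=DPPH0, aoh_known=AOH_KNOWN)


@pytest.fixture(scope="session")
def fit_cfg():
    return dk.FitConfig(seed=1)


@pytest.fixture(scope="session")
def sinapic_trace():
    """Noiseless one-reaction decay at the standard 10 µM assay setting."""
    params = dk.RateParameters(k1=SINAPIC_K1, include_side=False)
    return dk.simulate_decay(
        params, dk.InitialState(dpph0=DPPH0, aoh0=SINAPIC_AOH0),
        dk.TimeGrid.regular(300.0),
    )


@pytest.fixture(scope="session")
def gallic_trace():
    """Noiseless two-reaction decay at the gallic-acid-like setting."""
    params = dk.RateParameters(k1=GALLIC_K1, k2=GALLIC_K2, include_side=True)
    return dk.simulate_decay(
        params, dk.InitialState(dpph0=DPPH0, aoh0=GALLIC_AOH0),
        dk.TimeGrid.regular(180.0),
    )


def as_conc_trace(trace):
    """DPPH-channel-only view of a simulated trace, as a fit would see it."""
    z = np.zeros_like(trace.dpph)
    return dk.ConcentrationTrace(times=trace.times, dpph=trace.dpph, aoh=z, ao=z)
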