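import numpy as np
import pytest

from glottifit import (
    FitVariables,
    StandardParameters,
    apply_scaling,
    generate_analytic_pair,
    simulate,
)


@pytest.fixture(scope="session")
def std():
    return StandardParameters()


@pytest.fixture(scope="session")
def effective_std(std):
    """Standard parameters at identity scaling, Ps = 8 cmH2O."""
    return apply_scaling(std, FitVariables(1.0, 1.0, 8.0))


@pytest.fixture(scope="session")
def standard_sim():
    """Symmetric standard-parameter simulation, shared across tests."""
    return simulate(FitVariables(1.0, 1.0, 8.0))


@pytest.fixture(scope="session")
def asymmetric_sim():
    """Mildly asymmetric driven simulation, shared across tests."""
    return simulate(FitVariables(1.2, 1.1, 15.0))


@pytest.fixture
def tone_pair():
    """Raised 200 Hz sinusoid pair (on-grid, no clipping)."""
    return generate_analytic_pair(200.0, amp_l=0.03, amp_r=0.025, offset=0.04)


@pytest.fixture
def clipped_pair():
    """Clipped 200 Hz sinusoid pair spending 20% of each cycle closed."""
    return generate_analytic_pair(200.0, amp_l=0.03, amp_r=0.03, closure_fraction=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
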