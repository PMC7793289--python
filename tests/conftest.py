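import warnings

import pytest

from ptmcycle.io import reference_parameters


@pytest.fixture
def params_unsat():
    """Reference kinetics, unsaturated regime (K_M = 10 x [S]_T)."""
    return reference_parameters("unsaturated")


@pytest.fixture
def params_sat_q():
    """Reference kinetics saturated through the synthesis rate Q."""
    return reference_parameters("saturated_Q")


@pytest.fixture
def fast_turnover(params_unsat):
    """Hundredfold-faster turnover at the same [S]_T and saturation level.

    Used where wall-clock relaxation time matters (stochastic runs,
    truncation sweeps): delta and Q are scaled together so Q/delta1,
    Q/delta2 and [S]_T/K_M are unchanged.
    """
    return params_unsat.replace(delta1=2e-3, delta2=2e-2, Q=2.0, D_total=1.0)


@pytest.fixture(autouse=True)
def _quiet_enzyme_regime_warning():
    """Scans sweep r into enzyme-rich corners by design; keep logs clean."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="enzyme totals exceed 10%")
        yield
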