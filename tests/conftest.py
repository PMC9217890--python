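import warnings

import numpy as np
import pytest

from methadone_qivive import pbk


@pytest.fixture(scope="session")
def caucasian_r_params():
    return pbk.default_parameters("Caucasian", "R")


@pytest.fixture(scope="session")
def caucasian_s_params():
    return pbk.default_parameters("Caucasian", "S")


@pytest.fixture(scope="session")
def caucasian_r_sim(caucasian_r_params):
    """One reference 30-day simulation at the 30 mg/day study dose."""
    return pbk.simulate(caucasian_r_params, 30.0, 30)


def unbound_cmax(params, dose, n_days=30, rtol=1e-6):
    """Unbound steady-state Cmax, silencing the steady-state warning."""
    res = pbk.simulate(params, dose, n_days, rtol=rtol, atol=rtol * 1e-2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", pbk.SteadyStateWarning)
        return pbk.steady_state_cmax(res)[1]


def coeffs_to_batch(coeffs, n):
    """Tile scalar model coefficients into batch arrays of size n."""
    return dict(
        V=np.tile(coeffs.V, (n, 1)), Q=np.tile(coeffs.Q, (n, 1)),
        P=np.tile(coeffs.P, (n, 1)), q_tot=np.full(n, coeffs.q_tot),
        ka=np.full(n, coeffs.ka), fa=np.full(n, coeffs.fa),
        rcl=np.full(n, coeffs.rcl), fu_b=np.full(n, coeffs.fu_b),
        vmax_vivo=np.tile(coeffs.vmax_vivo, (n, 1)),
        km=np.tile(coeffs.km, (n, 1)),
    )
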