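"""Shared fixtures: analytic single-compartment (RC) patients.

A "single-compartment" patient is built from 100 identical compartments
with the linear PV limit (beta = 0); in parallel they behave exactly like
one RC element with R = r_central + r_b/100 and C = 100 * c0, which gives
closed-form pressure, flow and volume trajectories to test against.
"""

import numpy as np
import pytest

from aprvdp import ModelConfig, VirtualPatient


@pytest.fixture
def linear_config():
    """Linear-PV configuration with symmetric in/expiratory resistance."""
    return ModelConfig(beta=0.0, exp_factor=1.0, r_central=0.5)


def make_uniform_patient(r_b=950.0, k_stiff=0.0, top=5.0, p_ext=0.0):
    n = 100
    return VirtualPatient(
        p_ext=np.full(n, float(p_ext)),
        k_stiff=np.full(n, float(k_stiff)),
        top=np.full(n, float(top)),
        r_b=np.full(n, float(r_b)),
    )


@pytest.fixture
def rc_patient():
    """Uniform linear patient: R = 0.5 + 9.5 = 10 cmH2O/(L/s), C = 50
    mL/cmH2O, so tau = R*C = 0.5 s (plus the dt/C implicit-solver term)."""
    return make_uniform_patient(r_b=950.0)
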