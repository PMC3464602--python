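import numpy as np
import pytest

from triolike import RiskParams, SimDesign, UnitType


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_risk_params(rng, sigma=0.4):
    """A generic interior point of the full risk-parameter space."""
    v = np.exp(rng.normal(0.0, sigma, size=14))
    return RiskParams(
        R1=v[0], R2=v[1], S1=v[2], S2=v[3], Im=v[4], Ip=v[5],
        gamma={
            (0, 1): v[6], (0, 2): v[7], (1, 0): v[8], (1, 1): v[9],
            (1, 2): v[10], (2, 0): v[11], (2, 1): v[12], (2, 2): v[13],
        },
    )


#: the six-unit mixed design of the likelihood-comparison experiments
MIXED_UNITS = {
    UnitType.CASE_PARENT_TRIO: 50,
    UnitType.CASE_MOTHER_DUO: 50,
    UnitType.CASE_FATHER_DUO: 50,
    UnitType.CONTROL_PARENTAL_MATING: 50,
    UnitType.CONTROL_MOTHER_DUO: 50,
    UnitType.CONTROL_FATHER_DUO: 50,
}


@pytest.fixture
def mixed_design():
    return SimDesign(n_units=dict(MIXED_UNITS), risk=RiskParams(R2=2.0), q=0.3, seed=11)
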