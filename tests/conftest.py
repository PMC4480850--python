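import pytest

from antenna import AntennaParameters


@pytest.fixture(scope="session")
def moderate_params() -> AntennaParameters:
    """Small-rate parameter set where every solver route is cheap: mean ~28
    subunits, relaxation ~20 s, a few hundred events per trajectory."""
    return AntennaParameters(r=5.0, d=3.0, w=0.05, k_off=2.0)


@pytest.fixture(scope="session")
def moderate_oracle(moderate_params):
    from antenna import solve_stationary

    dist, cme = solve_stationary(moderate_params)
    return dist, cme


def z_score(estimate: float, truth: float, se: float) -> float:
    return abs(estimate - truth) / se
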