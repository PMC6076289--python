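import numpy as np
import pytest

from mrafit.ode_models import RateModel, build_mapk_egf_model
from mrafit.synthetic_data import simulate_experiment


def make_linear_chain(u=2.0, a=1.0, b=3.0, c=2.0) -> RateModel:
    """Two-node linear cascade with closed-form steady state (u/a, b*u/(a*c)).

    f1 = u - a*x1, f2 = b*x1 - c*x2; constant Jacobian [[-a, 0], [b, -c]].
    """
    def rate(x, t=0.0):
        return np.array([u - a * x[0], b * x[1 - 1] - c * x[1]])

    def jac(x, t=0.0):
        return np.array([[-a, 0.0], [b, -c]])

    return RateModel(
        species_names=["n1", "n2"],
        rate=rate,
        totals=[1e6, 1e6],  # effectively unbounded
        parameters={"u": u, "a": a, "b": b, "c": c},
        jacobian=jac,
    )


@pytest.fixture
def linear_chain():
    return make_linear_chain()


@pytest.fixture(scope="session")
def egf_model():
    """EGF-driven cascade at its published parameters, lowest study dose."""
    return build_mapk_egf_model(egf=0.1)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Default simulated experiment: 4 doses, 50% knockdowns, sigma = 0."""
    return simulate_experiment(noise_sd=0.0, seed=1)
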