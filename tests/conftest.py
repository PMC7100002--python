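import numpy as np
import pytest

from sirmap import EpidemicState, ModelParameters


@pytest.fixture
def params_delta0() -> ModelParameters:
    """δ=0 endemic benchmark: R0 = 1.875, globally stable regime."""
    return ModelParameters(Lambda=20, beta=0.03, mu=0.01, delta=0.0, gamma=0.006)


@pytest.fixture
def params_delta() -> ModelParameters:
    """δ=0.001 endemic benchmark: R0 ≈ 1.765."""
    return ModelParameters(Lambda=20, beta=0.03, mu=0.01, delta=0.001,
                           gamma=0.006)


@pytest.fixture
def cascade_rates() -> ModelParameters:
    """Fixed rates of the period-doubling regime (β is swept via R0)."""
    return ModelParameters(Lambda=20, beta=1.0, mu=0.01, delta=0.001,
                           gamma=0.001)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230242)


def draw_feasible(rng: np.random.Generator, *, r0_below_one: bool | None = None
                  ) -> tuple[ModelParameters, EpidemicState]:
    """A random parameter set satisfying the feasibility conditions plus a
    random start inside the invariant domain Ω1."""
    while True:
        mu = rng.uniform(0.001, 0.3)
        delta = rng.uniform(0, 0.2)
        gamma = rng.uniform(0, 0.4)
        beta = rng.uniform(0, 0.95)
        if beta + mu >= 1 or mu + delta + gamma >= 1:
            continue
        r0 = beta / (mu + delta + gamma)
        if r0_below_one is True and r0 >= 1:
            continue
        if r0_below_one is False and r0 <= 1:
            continue
        break
    Lam = rng.uniform(1, 100)
    params = ModelParameters(Lam, beta, mu, delta, gamma)
    cap = Lam / mu
    fracs = rng.dirichlet([1, 1, 1, 1])  # last share left empty
    state = EpidemicState(*(cap * fracs[:3]))
    return params, state
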