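import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import valuedp as vd

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometric_policy() -> vd.PolicyGrid:
    """Geometric discounting gamma=0.1, logistic utility m=4, s=3.5 (standard grid)."""
    cfg = vd.BellmanConfig(
        cost_regime="geometric", gamma=0.1, utility=vd.logistic_utility(4.0, 3.5)
    )
    return vd.solve_policy(cfg)


@pytest.fixture(scope="session")
def geometric02_policy() -> vd.PolicyGrid:
    """Geometric discounting gamma=0.2 (the boundary-triangle parameterisation)."""
    cfg = vd.BellmanConfig(
        cost_regime="geometric", gamma=0.2, utility=vd.logistic_utility(4.0, 3.5)
    )
    return vd.solve_policy(cfg)


@pytest.fixture(scope="session")
def linear_logistic_policy() -> vd.PolicyGrid:
    """Bayes-Risk regime, c=0, calibrated reward rate, logistic utility m=4, s=3.5."""
    cfg = vd.BellmanConfig(cost_regime="linear", c=0.0, utility=vd.logistic_utility(4.0, 3.5))
    return vd.solve_policy(cfg)


@pytest.fixture(scope="session")
def linear_linear_policy() -> vd.PolicyGrid:
    """Bayes-Risk regime, c=0, calibrated reward rate, linear utility."""
    cfg = vd.BellmanConfig(cost_regime="linear", c=0.0, utility=vd.linear_utility())
    return vd.solve_policy(cfg)


def make_stub_policy(cfg: vd.BellmanConfig, margin_value: float) -> vd.PolicyGrid:
    """Hand-built policy whose margin is constant: <=0 decides everywhere, >0 never."""
    times = cfg.times()
    shape = (times.size,) + (cfg.grid_n,) * cfg.n_options
    return vd.PolicyGrid(
        times=times,
        values=np.zeros(shape),
        actions=np.zeros(shape, dtype=np.int8),
        margin=np.full(shape, margin_value),
        config=cfg,
    )


@pytest.fixture
def small_geometric_cfg() -> vd.BellmanConfig:
    return vd.BellmanConfig(
        cost_regime="geometric",
        gamma=0.2,
        utility=vd.logistic_utility(4.0, 3.5),
        grid_n=11,
        dt=0.1,
        horizon=0.5,
    )
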