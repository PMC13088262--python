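import numpy as np
import pytest
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge

from ctloop.condition_space import ConditionCategory, ConditionSpace, Scheme
from ctloop.oracle import OracleParams
from ctloop.surrogate import ModelRegistry


@pytest.fixture
def tiny_space() -> ConditionSpace:
    """All-categorical 3x3x3 space (27 schemes) for brute-force comparisons."""
    return ConditionSpace(
        space_id="tiny",
        categories=(
            ConditionCategory("a", "categorical", levels=("a0", "a1", "a2")),
            ConditionCategory("b", "categorical", levels=("b0", "b1", "b2")),
            ConditionCategory("c", "categorical", levels=("c0", "c1", "c2")),
        ),
    )


@pytest.fixture
def tiny_oracle(tiny_space) -> OracleParams:
    """Additive noise-controllable surface on the tiny space; optimum (a1, b0, c2)."""
    return OracleParams(
        space=tiny_space,
        optimum=Scheme(assignments={"a": "a1", "b": "b0", "c": "c2"}),
        ct_opt=26.0,
        level_penalties={
            "a": {"a0": 1.5, "a1": 0.0, "a2": 2.5},
            "b": {"b0": 0.0, "b1": 0.8, "b2": 3.0},
            "c": {"c0": 2.0, "c1": 1.0, "c2": 0.0},
        },
        noise_sigma_auto=0.065,
        noise_sigma_hitl=0.40,
    )


@pytest.fixture
def mixed_space() -> ConditionSpace:
    """One categorical + one numeric category, as in the worked encoding example."""
    return ConditionSpace(
        space_id="mixed",
        categories=(
            ConditionCategory("A", "categorical", levels=("level1", "level2", "level3")),
            ConditionCategory("B", "numeric", range=(200.0, 1000.0), units="nm"),
        ),
    )


@pytest.fixture
def fast_registry() -> ModelRegistry:
    """Three cheap models so loop tests stay fast."""
    return ModelRegistry(
        {
            "random_forest": lambda seed: RandomForestRegressor(
                n_estimators=30, random_state=seed, n_jobs=1
            ),
            "ridge": lambda seed: Ridge(alpha=1.0),
            "baseline_mean": lambda seed: DummyRegressor(strategy="mean"),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
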