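"""Shared fixtures: configurations and precomputed base-case totals."""

import pytest
from hypothesis import HealthCheck, settings

import osteocea as oc

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture()
def cfg():
    """A fresh default configuration (function-scoped: safe to mutate)."""
    return oc.generate_config(seed=0)


@pytest.fixture(scope="session")
def base_cfg():
    """Shared read-only default configuration."""
    return oc.generate_config(seed=0)


@pytest.fixture(scope="session")
def base_totals(base_cfg):
    """Base-case totals for all six packaged strategies."""
    return oc.run_all(base_cfg)


@pytest.fixture(scope="session")
def two_strategy_cfg():
    """Alendronate + denosumab only, for fast sensitivity tests."""
    full = oc.generate_config(seed=0)
    cfg = full.model_copy(deep=True)
    cfg.strategies = [full.strategy("generic_alendronate"), full.strategy("denosumab")]
    return cfg
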