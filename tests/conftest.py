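import numpy as np
import pytest

from driverattn.simulate import GeneratorConfig, generate_study


def small_config(**overrides) -> GeneratorConfig:
    """A desk-scale study: 1-2 participants, short periods, few arrows."""
    kwargs = dict(
        n_participants=1,
        n_periods=2,
        period_duration=130.0,
        arrows_per_period=10,
        outcome_split=(2, 0, 0),
        seed=7,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def small_study():
    """One tiny signal-level study shared across feature tests."""
    cfg = small_config()
    sessions, gt = generate_study(cfg)
    return cfg, sessions, gt


@pytest.fixture(scope="session")
def medium_study():
    """One participant at full drive scale (two 10-min periods, 20 unreliable
    trials) — enough trials for rank-correlation checks of feature recovery."""
    cfg = GeneratorConfig(n_participants=1, n_periods=2, seed=23)
    sessions, gt = generate_study(cfg)
    return cfg, sessions, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
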