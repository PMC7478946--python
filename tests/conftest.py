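"""Shared fixtures: small synthetic studies so model fits stay fast."""

from dataclasses import replace

import pytest

from choicetrace import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """16 participants x 8 foods (28 trials each): fast unit-test scale."""
    return SimConfig(n_participants=16, n_foods=8, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_model_input(small_study):
    return small_study.model_input()


@pytest.fixture(scope="session")
def medium_study():
    """30 participants x 12 foods (66 trials): large enough for sign checks."""
    return simulate_study(SimConfig(n_participants=30, n_foods=12, seed=7))


@pytest.fixture(scope="session")
def medium_model_input(medium_study):
    return medium_study.model_input()


def zero_variance_config(**overrides) -> SimConfig:
    """All random-effect variances zero: single-level GLM oracle territory."""
    base = dict(
        choice_re_var=0.0, choice_health_slope=0.0,
        auc_tau00=0.0, xflip_tau00=0.0, pal_tau00=0.0,
        timeout_rate=0.0,
    )
    base.update(overrides)
    return replace(SimConfig(), **base)
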