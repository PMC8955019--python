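from dataclasses import replace

import numpy as np
import pytest

from sizebias import PopulationParams, StudyConfig, build_trial_table, plan_blocks


@pytest.fixture(scope="session")
def default_config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def clean_population() -> PopulationParams:
    """Population with no planted bad observers (for recovery tests)."""
    return replace(PopulationParams(), n_high_weber=0, n_degenerate=0)


@pytest.fixture()
def blocked_table(default_config):
    return plan_blocks(build_trial_table(default_config, "p1"), default_config, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def make_binomial_responses(mu, sigma, levels, n_per_level, rng):
    """Trial-level (x, y) arrays drawn from a cumulative-Gaussian observer."""
    from sizebias import psychometric_probability

    x = np.repeat(np.asarray(levels, dtype=float), n_per_level)
    y = rng.random(len(x)) < psychometric_probability(x, mu, sigma)
    return x, y
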