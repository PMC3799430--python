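"""Shared fixtures: small seeded synthetic cohorts and pipeline runs."""

import numpy as np
import pandas as pd
import pytest

from aberlink.pipeline import PipelineParams, run_pipeline
from aberlink.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Half-scale study conditions: same effect sizes and noise, fewer
    samples/genes, so the whole suite stays fast."""
    return SimConfig().scaled(0.5)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate(small_config, seed=11)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    ds, truth = small_cohort
    return run_pipeline(ds, PipelineParams()), truth


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort under the default study conditions."""
    return generate(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def toy_clinical():
    rng = np.random.default_rng(5)
    n = 80
    samples = [f"P{i:02d}" for i in range(n)]
    return pd.DataFrame(
        {
            "survival_days": rng.exponential(400, n),
            "event": (rng.random(n) < 0.7).astype(int),
        },
        index=samples,
    )
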