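from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lattice123.config import PipelineConfig
from lattice123.data import SynthConfig, generate_synthetic

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_collection():
    """Small, fast synthetic collection: 3 channels, 20 epochs, 256 samples."""
    return generate_synthetic(
        SynthConfig(
            n_channels=3,
            n_epochs_healthy=14,
            n_epochs_ad=6,
            n_samples=256,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def tiny_config() -> PipelineConfig:
    return PipelineConfig(iv=20, fv=60, folds=5, seed=3)
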