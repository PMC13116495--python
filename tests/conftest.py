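import numpy as np
import pytest

from ppcsurv import (
    EncoderConfig,
    PipelineConfig,
    RFHeadConfig,
    TrainingConfig,
    default_schema,
    generate_cohort,
    make_config,
    train_hybrid,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate paper-like cohort shared by read-only tests."""
    return generate_cohort(make_config(400, 0.2, "paperlike", seed=0))


@pytest.fixture(scope="session")
def separable_cohort():
    return generate_cohort(make_config(800, 0.2, "separable", seed=1))


def fast_pipeline_config(seed: int = 0, **kwargs) -> PipelineConfig:
    """Small architecture for unit tests (full defaults are exercised in the
    acceptance suite)."""
    return PipelineConfig(
        encoder=EncoderConfig(hidden1=64, hidden2=32, embedding_dim=4, seed=seed),
        training=TrainingConfig(
            batch_size=128, max_epochs=12, warmup_epochs=3,
            early_stopping_patience=4, seed=seed,
        ),
        rf_head=RFHeadConfig(n_trees=80, max_depth=8, seed=seed),
        prelim_rf_trees=50,
        prelim_rf_depth=5,
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def trained_model(small_cohort):
    """One trained hybrid model reused by inference-contract tests."""
    return train_hybrid(small_cohort, fast_pipeline_config(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
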