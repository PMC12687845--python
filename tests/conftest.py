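import numpy as np
import pytest

from latentaug import (
    DownsampleCodec,
    FixtureConfig,
    TrainConfig,
    VaeConfig,
    generate_fixture_dataset,
    train_vae,
)


@pytest.fixture(scope="session")
def small_cohort():
    """16-patient, 32 px cohort for fast unit tests."""
    return generate_fixture_dataset(
        FixtureConfig(n_patients=16, image_side=32, seed=11)
    )


@pytest.fixture(scope="session")
def cohort64():
    """Default-scale cohort (64 px) used by pipeline-level tests."""
    return generate_fixture_dataset(FixtureConfig(n_patients=20, seed=7))


@pytest.fixture(scope="session")
def trained_vae(small_cohort):
    """A codec trained once per session on the small cohort."""
    cfg = VaeConfig(input_side=32, epochs=60, latent_dim=16, hidden=128, seed=3)
    vae, trace = train_vae(small_cohort, cfg)
    return vae, trace


@pytest.fixture()
def dummy_codec():
    """Trivial block-mean codec satisfying the codec contract (no training)."""
    return DownsampleCodec(input_side=32, grid=8)


@pytest.fixture()
def dummy_codec64():
    return DownsampleCodec(input_side=64, grid=8)


@pytest.fixture()
def fast_train_config():
    return TrainConfig(epochs=3, seed=0)
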