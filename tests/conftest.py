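import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """Noiseless tiny fixture bundle written once per session."""
    from swaps.simulate import write_fixture_bundle

    out = tmp_path_factory.mktemp("tiny")
    paths = write_fixture_bundle(out, preset="tiny", seed=1, force=True)
    return paths


@pytest.fixture(scope="session")
def tiny_oracle_result(tiny_bundle):
    """Pipeline run on the tiny bundle with oracle label-rectangle masks."""
    from swaps.config import RunConfig
    from swaps.pipeline import execute

    cfg = RunConfig.from_yaml(tiny_bundle["config"])
    cfg.mask_mode = "oracle"
    return cfg, execute(cfg)


@pytest.fixture(scope="session")
def separable_pool():
    """Separable fixture suite: target images with in-window peaks at the
    positive hint, decoy images without signal."""
    from swaps.simulate import make_separable_model_pool

    return make_separable_model_pool(40, seed=3)


@pytest.fixture(scope="session")
def toy_train_config():
    from swaps.config import RunConfig

    return RunConfig(random_seed=3, image_size=64, unet_depth=3,
                     unet_base_channels=8, epochs=30, patience=8, batch_size=16)


@pytest.fixture(scope="session")
def trained_segmentation(separable_pool, toy_train_config):
    from swaps.models import train_segmentation

    return train_segmentation(separable_pool["segmentation_pairs"], toy_train_config)


@pytest.fixture(scope="session")
def trained_scorer(separable_pool, trained_segmentation, toy_train_config):
    from swaps._nn import sigmoid
    from swaps.models import ModelInput, train_scorer

    seg_model, _ = trained_segmentation
    pool = []
    for minput, label, cid in separable_pool["score_items"]:
        prob = sigmoid(seg_model.forward(minput.channels[None]))[0]
        pool.append((ModelInput(np.concatenate([minput.channels, prob[None]]), cid), label))
    model, report = train_scorer(pool, toy_train_config)
    return model, report, pool
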