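"""Shared fixtures: trained tiny models and full-geometry builds.

Session-scoped because network training, although small, dominates the
suite's runtime; every test that needs a fitted model shares these.
"""

import numpy as np
import pytest

from gidfe import (
    ArchitectureSpec,
    PipelineConfig,
    TrainConfig,
    build_model,
    make_images,
    run_pipeline,
    train_model,
)


@pytest.fixture(scope="session")
def images_4class():
    """4-class, 25-per-class, 128-px synthetic image set."""
    return make_images(4, 25, size=128, seed=1)


@pytest.fixture(scope="session")
def trained_4class(images_4class):
    """Tiny network fitted to the 4-class set (reaches 100% train acc)."""
    model = build_model(ArchitectureSpec.tiny(128), 4, seed=1)
    train_model(model, images_4class,
                cfg=TrainConfig(max_epochs=10, batch_size=32, seed=0))
    assert model.history[-1]["train_acc"] > 0.9
    return model


@pytest.fixture(scope="session")
def images_8class():
    """8-class, 5-per-class, 64-px synthetic image set."""
    return make_images(8, 5, size=64, seed=7)


@pytest.fixture(scope="session")
def full_star_model():
    """Untrained full-geometry (224-input) ResNet50* build."""
    return build_model(ArchitectureSpec(), 8, seed=0)


@pytest.fixture(scope="session")
def full_plain_model():
    """Untrained full-geometry standard ResNet-50 build."""
    return build_model(ArchitectureSpec(variant="resnet50"), 8, seed=0)


@pytest.fixture(scope="session")
def pipeline_run():
    """One deterministic end-to-end pipeline run on small fixtures."""
    cfg = PipelineConfig(
        fixture={"n_classes": 4, "n_per_class": 10},
        arch=ArchitectureSpec.tiny(64),
        train=TrainConfig(max_epochs=8, batch_size=32),
        sv=2,
        fv=20,
        seed=1,
    )
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
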