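"""Shared fixtures.

The heavy session-scoped fixtures train the scaled-down models once and are
shared by the learning/comparison tests. Problem sizes (canvas, epochs) are
the package's desk-scale study conditions; see docs/methods.md.
"""

import numpy as np
import pytest

from leafseg.synthetic import ARTIFACTS, generate_leaf, small_leaf_params

ARTIFACT_SET = frozenset(ARTIFACTS)

# Desk-scale canvases: the tracer uses a larger leaf so the 64-px tile to
# leaf-size ratio stays close to the full-scale geometry (256-px tiles on
# ~1800-px leaves); vein work uses a mid-size canvas, and the model
# comparison uses a smaller one so twenty images stay affordable.
TRACER_CANVAS = (320, 240)
VEIN_CANVAS = (256, 192)
EVAL_CANVAS = (160, 120)


@pytest.fixture(scope="session")
def tracer_train_leaves():
    return [generate_leaf(small_leaf_params(seed=s, canvas_size=TRACER_CANVAS))
            for s in range(6)]


@pytest.fixture(scope="session")
def tracer_heldout_leaves():
    return [generate_leaf(small_leaf_params(seed=s, canvas_size=TRACER_CANVAS))
            for s in (6, 7)]


@pytest.fixture(scope="session")
def vein_train_leaves():
    # Two of six training leaves carry scan artifacts, mirroring iterative
    # dataset refinement (artifact examples added so models learn them).
    return [generate_leaf(small_leaf_params(
        seed=s, canvas_size=VEIN_CANVAS,
        artifact_flags=(ARTIFACT_SET if s >= 4 else frozenset())))
        for s in range(6)]


@pytest.fixture(scope="session")
def vein_heldout_leaves():
    return [generate_leaf(small_leaf_params(seed=s, canvas_size=VEIN_CANVAS))
            for s in (6, 7)]


@pytest.fixture(scope="session")
def ordering_eval_leaves():
    # Model comparison happens on artifact-bearing scans (the regime where
    # segmentations fragment); margin equals the grower tile radius.
    return [generate_leaf(small_leaf_params(
        seed=100 + s, canvas_size=EVAL_CANVAS, margin=16,
        artifact_flags=ARTIFACT_SET))
        for s in range(20)]


@pytest.fixture(scope="session")
def trained_tracer(tracer_train_leaves):
    from leafseg.tracer import (AugmentConfig, TracerTrainConfig,
                                build_tracer_dataset, small_tracer_config,
                                train_tracer)

    cfg = small_tracer_config()
    ds = build_tracer_dataset(
        [(s.image, s.leaf_mask) for s in tracer_train_leaves], cfg,
        AugmentConfig(jitter_px=3))
    model, history = train_tracer(ds, TracerTrainConfig(
        epochs=40, batch_size=64, batches_per_epoch=12, lr=2e-3,
        patience=20, n_val_batches=2, seed=0))
    return model, history


@pytest.fixture(scope="session")
def grower_dataset(vein_train_leaves):
    from leafseg.grower import build_grower_dataset, small_grower_config

    return build_grower_dataset(
        [(s.image, s.vein_mask, s.leaf_mask) for s in vein_train_leaves],
        small_grower_config(), seed=0)


@pytest.fixture(scope="session")
def trained_growers(grower_dataset):
    from leafseg.grower import (GrowLossConfig, GrowerTrainConfig,
                                train_grower)

    models = {}
    for mode in ("focal", "bce"):
        models[mode], _ = train_grower(
            grower_dataset,
            GrowerTrainConfig(epochs=30, batch_size=128,
                              batches_per_epoch=12, lr=1e-2,
                              lr_decay_at=0.5, lr_decay_factor=0.1, seed=0),
            GrowLossConfig(mode=mode))
    return models


@pytest.fixture(scope="session")
def trained_unets(vein_train_leaves):
    from leafseg.grower import GrowLossConfig
    from leafseg.unet import (UNetTrainConfig, build_unet_dataset,
                              small_unet_config, train_unet)

    ds = build_unet_dataset(
        [(s.image, s.vein_mask & s.leaf_mask, s.leaf_mask)
         for s in vein_train_leaves], small_unet_config(32))
    models = {}
    for mode in ("focal", "bce"):
        models[mode], _ = train_unet(
            ds, UNetTrainConfig(epochs=20, batch_size=64,
                                batches_per_epoch=12, lr=2e-3, seed=0),
            GrowLossConfig(mode=mode))
    return models
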