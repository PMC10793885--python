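"""Shared fixtures: tiny desk-scale datasets and trained toy models.

Everything here is generated programmatically at test time; the heavier
session-scoped fixtures (the full mini-study) are shared across the
acceptance tests so the grid is trained exactly once per session.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from cxrfuse import (
    BackboneSpec,
    ExperimentConfig,
    SyntheticDatasetSpec,
    TrainingRunSpec,
    generate_dataset,
    make_backbone,
    run_experiment,
    train_model,
)

logging.getLogger("cxrfuse").setLevel(logging.ERROR)

TINY_BACKBONE = BackboneSpec(image_size=16, channels=(4, 8))
SMALL_BACKBONE = BackboneSpec(image_size=32, channels=(8, 16))


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticDatasetSpec:
    """Structural fixture: fast to generate, too small to learn from."""
    return SyntheticDatasetSpec(
        n_patients=40, images_per_patient=1, image_size=16, seed=5
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture(scope="session")
def tiny_backbone() -> BackboneSpec:
    return TINY_BACKBONE


@pytest.fixture(scope="session")
def small_bundle():
    """Learnable fixture: a cold-trained toy model reaches high MCC."""
    return generate_dataset(
        SyntheticDatasetSpec(
            n_patients=120, images_per_patient=1, image_size=32,
            class_separation=1.5, seed=5,
        )
    )


@pytest.fixture(scope="session")
def small_backbone() -> BackboneSpec:
    return SMALL_BACKBONE


@pytest.fixture(scope="session")
def trained_pair(small_bundle, small_backbone):
    """Two cold-trained toy models (different seeds) on the small bundle."""
    out = []
    for seed in (3, 4):
        spec = TrainingRunSpec(
            backbone=small_backbone, init_mode="cold-R", data_stage="F",
            max_epochs=10, lr=0.01, seed=seed,
        )
        weights, history, best_val = train_model(spec, small_bundle)
        out.append({"weights": weights, "history": history, "best_val": best_val})
    return out


@pytest.fixture(scope="session")
def mini_study_store(tmp_path_factory):
    """The full mini-study grid, trained once per session (several minutes)."""
    outdir = tmp_path_factory.mktemp("ministudy")
    config = ExperimentConfig()
    return config, run_experiment(config, outdir, until="report")


def tiny_model(backbone: BackboneSpec, weights):
    m = make_backbone(backbone)
    m.set_weights(weights)
    return m
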