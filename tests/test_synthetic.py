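"""Synthetic study data: splits, shifts, backbones, source pretraining."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cxrfuse import (
    BackboneSpec,
    ShiftParams,
    SyntheticDatasetSpec,
    TrainingRunSpec,
    generate_dataset,
    generate_external_shift,
    make_backbone,
    pretrain_source_task,
    train_model,
    weight_emd,
)
from cxrfuse.metrics import PredictionSet, evaluate_predictions, select_threshold_max_f
from cxrfuse.synthetic import export_dataset, cxr_mini_spec
from conftest import SMALL_BACKBONE, tiny_model


class TestSplitStructure:
    def test_class_counts_follow_the_imbalance(self):
        spec = SyntheticDatasetSpec(n_patients=120, images_per_patient=1,
                                    image_size=16, abnormal_fraction=2 / 3, seed=0,
                                    external_shifts={})
        bundle = generate_dataset(spec)
        all_labels = np.concatenate(
            [bundle.labels[k] for k in ("train_F", "val_F", "test")]
        )
        assert int(all_labels.sum()) == 80
        assert len(all_labels) == 120

    def test_70_10_20_patient_split_and_halving(self):
        spec = SyntheticDatasetSpec(n_patients=120, images_per_patient=1,
                                    image_size=16, seed=0, external_shifts={})
        bundle = generate_dataset(spec)
        assert len(bundle.labels["train_F"]) == 84
        assert len(bundle.labels["val_F"]) == 12
        assert len(bundle.labels["test"]) == 24
        assert len(bundle.labels["train_P"]) == 42

    def test_patient_level_disjointness(self, tiny_bundle):
        groups = {
            "train": set(tiny_bundle.patients["train_F"]),
            "val": set(tiny_bundle.patients["val_F"]),
            "test": set(tiny_bundle.patients["test"]),
        }
        assert not groups["train"] & groups["val"]
        assert not groups["train"] & groups["test"]
        assert not groups["val"] & groups["test"]

    def test_partial_stage_is_prefix_of_full(self, tiny_bundle):
        for split in ("train", "val"):
            part, full = tiny_bundle.images[f"{split}_P"], tiny_bundle.images[f"{split}_F"]
            assert len(part) == int(np.ceil(len(full) / 2))
            np.testing.assert_array_equal(part, full[: len(part)])

    def test_regeneration_is_bit_identical(self, tiny_spec, tiny_bundle):
        again = generate_dataset(tiny_spec)
        for key, imgs in tiny_bundle.images.items():
            np.testing.assert_array_equal(imgs, again.images[key])
            np.testing.assert_array_equal(tiny_bundle.labels[key], again.labels[key])

    def test_pixel_range_and_impossible_splits(self, tiny_bundle):
        for imgs in tiny_bundle.images.values():
            assert imgs.min() >= 0.0 and imgs.max() <= 1.0
        with pytest.raises(ValueError, match="70/10/20"):
            generate_dataset(SyntheticDatasetSpec(n_patients=3, image_size=16))


class TestExternalShift:
    def test_zero_shift_is_identity(self, tiny_bundle):
        x, y, p = generate_external_shift(tiny_bundle, ShiftParams(), seed=1)
        np.testing.assert_array_equal(x, tiny_bundle.images["test"])
        np.testing.assert_array_equal(y, tiny_bundle.labels["test"])

    def test_shift_is_deterministic_under_seed(self, tiny_bundle):
        shift = ShiftParams(0.1, 0.7, 1.0, 0.05)
        x1, _, _ = generate_external_shift(tiny_bundle, shift, seed=3)
        x2, _, _ = generate_external_shift(tiny_bundle, shift, seed=3)
        np.testing.assert_array_equal(x1, x2)

    def test_severe_shift_degrades_a_fixed_model(self, small_bundle, small_backbone,
                                                 trained_pair):
        model = tiny_model(small_backbone, trained_pair[0]["weights"])
        x_va, y_va = small_bundle.split("val_F")
        t = select_threshold_max_f(PredictionSet(model.predict_scores(x_va), y_va))
        x_te, y_te = small_bundle.split("test")
        internal = evaluate_predictions(
            PredictionSet(model.predict_scores(x_te), y_te), t
        ).mcc
        severe = ShiftParams(intensity_offset=0.2, contrast_scale=0.4,
                             blur_sigma=2.5, noise_sigma=0.06)
        x_ext, y_ext, _ = generate_external_shift(small_bundle, severe, seed=9)
        external = evaluate_predictions(
            PredictionSet(model.predict_scores(x_ext), y_ext), t
        ).mcc
        assert external <= internal


class TestBackbone:
    def test_seeded_init_is_identical(self):
        a = make_backbone(SMALL_BACKBONE, seed=7)
        b = make_backbone(SMALL_BACKBONE, seed=7)
        assert a.get_weights().content_hash() == b.get_weights().content_hash()

    def test_probability_output_shape(self):
        model = make_backbone(SMALL_BACKBONE, seed=0)
        p = model.predict_proba(np.random.default_rng(0).uniform(0, 1, (5, 32, 32)))
        assert p.shape == (5, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_gap_width_equals_final_channel_count(self):
        model = make_backbone(BackboneSpec(image_size=16, channels=(4, 6)), seed=0)
        assert model.feature_width == 6
        feats = model.features(np.zeros((2, 16, 16)))
        assert feats.shape == (2, 6)

    def test_undersized_image_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            make_backbone(BackboneSpec(image_size=10, channels=(4, 8, 16)))


class TestSourcePretraining:
    def test_deterministic_under_seed(self, tiny_backbone):
        a = pretrain_source_task(tiny_backbone, seed=6, n_images=32, epochs=1)
        b = pretrain_source_task(tiny_backbone, seed=6, n_images=32, epochs=1)
        assert a.content_hash() == b.content_hash()

    def test_pretraining_moves_the_weight_distribution(self, tiny_backbone):
        random_init = make_backbone(tiny_backbone, seed=6).get_weights()
        pretrained = pretrain_source_task(tiny_backbone, seed=6, n_images=64, epochs=2)
        assert weight_emd(random_init, pretrained) > 0.0


def test_null_signal_gives_chance_performance():
    """With zero effect size a trained model scores near-zero MCC on a
    200-sample held-out test."""
    backbone = BackboneSpec(image_size=16, channels=(4, 8))
    spec = SyntheticDatasetSpec(n_patients=1000, images_per_patient=1, image_size=16,
                                class_separation=0.0, seed=2, external_shifts={})
    bundle = generate_dataset(spec)
    assert len(bundle.labels["test"]) == 200
    run = TrainingRunSpec(backbone=backbone, init_mode="cold-R",
                          data_stage="F", max_epochs=4, lr=0.01, seed=0)
    weights, _, _ = train_model(run, bundle)
    model = tiny_model(backbone, weights)
    x_va, y_va = bundle.split("val_F")
    t = select_threshold_max_f(PredictionSet(model.predict_scores(x_va), y_va))
    x_te, y_te = bundle.split("test")
    mcc = evaluate_predictions(PredictionSet(model.predict_scores(x_te), y_te), t).mcc
    assert abs(mcc) <= 0.15


def test_standard_fixture_shape():
    spec = cxr_mini_spec(seed=3)
    assert spec.n_patients == 300
    assert spec.image_size == 64
    assert spec.abnormal_fraction == pytest.approx(0.67)
    assert set(spec.external_shifts) == {"adult", "ped18", "ped11", "ped2"}


def test_png_export_writes_manifest(tmp_path, tiny_bundle):
    outdir = export_dataset(tiny_bundle, tmp_path / "ds")
    manifest = pd.read_csv(outdir / "manifest.csv")
    assert set(manifest.columns) == {"sample_id", "patient_id", "label", "split"}
    assert len(manifest) == sum(len(v) for v in tiny_bundle.images.values())
    split = manifest["split"].iloc[0]
    assert (outdir / split / f"{manifest['sample_id'].iloc[0]}.png").exists()
    assert (outdir / "spec.yaml").exists()
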