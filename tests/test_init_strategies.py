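"""Shrink-and-perturb re-initialization, GP alpha search, training driver."""

import numpy as np
import pytest

from cxrfuse import (
    AlphaSearchConfig,
    ShrinkPerturbConfig,
    TrainingRunSpec,
    WeightCollection,
    build_alpha_objective,
    gp_optimize_alpha,
    make_backbone,
    shrink_perturb_weights,
    train_model,
)
from cxrfuse.synthetic import BackboneSpec


def _wc(values):
    return WeightCollection((("layer.W", np.asarray(values, dtype=float)),))


class TestShrinkPerturb:
    def test_pure_shrink_halves_weights(self):
        out = shrink_perturb_weights(_wc([1.0, -2.0]), ShrinkPerturbConfig(alpha=0.5, beta=0.0))
        np.testing.assert_allclose(out.get("layer.W"), [0.5, -1.0])

    def test_constant_noise_mode_adds_beta(self):
        cfg = ShrinkPerturbConfig(alpha=1.0, beta=0.01, noise_mode="constant")
        out = shrink_perturb_weights(_wc([1.0, -2.0]), cfg)
        np.testing.assert_allclose(out.get("layer.W"), [1.01, -1.99])

    def test_gaussian_mode_variance_algebra(self):
        """Var(alpha*W + noise) = alpha^2 + beta^2 for standard-normal W."""
        rng = np.random.default_rng(0)
        w = _wc(rng.normal(0, 1, 10_000))
        cfg = ShrinkPerturbConfig(alpha=0.7209, beta=0.01, seed=1)
        out = shrink_perturb_weights(w, cfg)
        expected = 0.7209**2 + 0.01**2
        assert np.var(out.get("layer.W")) == pytest.approx(expected, rel=0.05)

    def test_identity_at_alpha_one_beta_zero(self):
        w = _wc([0.3, -0.7, 2.0])
        out = shrink_perturb_weights(w, ShrinkPerturbConfig(alpha=1.0, beta=0.0))
        assert out.allclose(w)

    def test_seeded_noise_is_reproducible(self):
        w = _wc(np.arange(5.0))
        cfg = ShrinkPerturbConfig(alpha=0.5, beta=0.1, seed=42)
        assert shrink_perturb_weights(w, cfg).allclose(shrink_perturb_weights(w, cfg))

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            ShrinkPerturbConfig(alpha=0.0)


class TestGPAlphaSearch:
    def test_recovers_quadratic_minimum(self):
        cfg = AlphaSearchConfig(n_calls=30, n_random_starts=10, seed=0)
        best, history = gp_optimize_alpha(lambda a: (a - 0.5) ** 2, cfg)
        assert abs(best - 0.5) < 0.05
        assert len(history) == 30

    def test_flat_landscape_returns_point_in_bounds(self):
        cfg = AlphaSearchConfig(n_calls=12, n_random_starts=6, seed=1)
        best, history = gp_optimize_alpha(lambda a: 1.0, cfg)
        assert 0.1 <= best <= 0.9
        assert min(loss for _, loss in history) == 1.0

    def test_boundary_minimum_of_monotone_objective(self):
        cfg = AlphaSearchConfig(n_calls=30, n_random_starts=10, seed=2)
        best, _ = gp_optimize_alpha(lambda a: -a, cfg)
        assert abs(best - 0.9) < 0.05

    def test_every_evaluation_stays_in_bounds(self):
        cfg = AlphaSearchConfig(n_calls=20, n_random_starts=5, seed=3)
        best, history = gp_optimize_alpha(lambda a: np.sin(20 * a), cfg)
        assert all(0.1 <= a <= 0.9 for a, _ in history)
        assert 0.1 <= best <= 0.9

    def test_objective_failure_reports_alpha(self):
        def bad(a):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="alpha="):
            gp_optimize_alpha(bad, AlphaSearchConfig(n_calls=5, n_random_starts=2, seed=0))

    def test_random_starts_cannot_exceed_calls(self):
        with pytest.raises(ValueError):
            AlphaSearchConfig(n_calls=5, n_random_starts=6)


class TestTrainingDriver:
    def test_zero_epochs_returns_initialization(self, tiny_bundle, tiny_backbone):
        spec = TrainingRunSpec(backbone=tiny_backbone, init_mode="cold-R",
                               data_stage="P", max_epochs=0, seed=9)
        weights, history, best_val = train_model(spec, tiny_bundle)
        model = make_backbone(tiny_backbone, seed=9)
        assert weights.allclose(model.get_weights())
        assert len(history) == 1
        assert best_val == history[0]["val_loss"]

    def test_loss_decreases_on_learnable_data(self, small_bundle, small_backbone):
        spec = TrainingRunSpec(backbone=small_backbone, init_mode="cold-R",
                               data_stage="F", max_epochs=10, lr=0.01, seed=1)
        _, history, best_val = train_model(spec, small_bundle)
        assert best_val < history[0]["val_loss"]

    def test_checkpoint_is_argmin_of_validation_history(self, trained_pair):
        for run in trained_pair:
            val_losses = [h["val_loss"] for h in run["history"]]
            assert run["best_val"] == pytest.approx(min(val_losses))

    def test_warm_start_resumes_at_source_val_loss(self, small_bundle, small_backbone,
                                                   trained_pair):
        source = trained_pair[0]
        spec = TrainingRunSpec(backbone=small_backbone, init_mode="warm", data_stage="F",
                               source=source["weights"], max_epochs=0, seed=2)
        _, history, best_val = train_model(spec, small_bundle)
        assert history[0]["val_loss"] == pytest.approx(source["best_val"], abs=1e-9)

    def test_seeded_training_is_bit_identical(self, tiny_bundle, tiny_backbone):
        spec = TrainingRunSpec(backbone=tiny_backbone, init_mode="cold-R",
                               data_stage="P", max_epochs=3, seed=21)
        w1, _, _ = train_model(spec, tiny_bundle)
        w2, _, _ = train_model(spec, tiny_bundle)
        assert w1.content_hash() == w2.content_hash()

    def test_incompatible_source_names_first_mismatched_layer(self, tiny_bundle):
        other = make_backbone(BackboneSpec(image_size=16, channels=(3, 8)), seed=0)
        spec = TrainingRunSpec(backbone=BackboneSpec(image_size=16, channels=(4, 8)),
                               init_mode="warm", data_stage="P",
                               source=other.get_weights(), max_epochs=1)
        with pytest.raises(ValueError, match="conv1"):
            train_model(spec, tiny_bundle)

    def test_source_required_for_dependent_modes(self):
        for mode in ("cold-I", "warm", "shrink"):
            with pytest.raises(ValueError, match="source"):
                TrainingRunSpec(init_mode=mode)


class TestAlphaObjective:
    def test_identity_alpha_zero_epochs_matches_source_loss(
        self, small_bundle, small_backbone, trained_pair
    ):
        source = trained_pair[0]["weights"]
        spec = TrainingRunSpec(backbone=small_backbone, init_mode="shrink", data_stage="F",
                               source=source, beta=0.0, max_epochs=0, seed=5)
        objective = build_alpha_objective(source, small_bundle, spec)
        model = make_backbone(small_backbone)
        model.set_weights(source)
        x_va, y_va = small_bundle.split("val_F")
        assert objective(1.0) == pytest.approx(model.loss_on(x_va, y_va))

    def test_objective_is_deterministic_per_alpha(self, small_bundle, small_backbone,
                                                  trained_pair):
        source = trained_pair[0]["weights"]
        spec = TrainingRunSpec(backbone=small_backbone, init_mode="shrink", data_stage="F",
                               source=source, max_epochs=2, seed=5)
        obj = build_alpha_objective(source, small_bundle, spec)
        assert obj(0.5) == pytest.approx(obj(0.5))

    def test_shrinking_helps_a_corrupted_checkpoint(self, small_bundle, small_backbone,
                                                    trained_pair):
        """Shrinking an inverted, sharpened checkpoint beats keeping it."""
        corrupted = trained_pair[0]["weights"].map(lambda n, t: -3.0 * t)
        spec = TrainingRunSpec(backbone=small_backbone, init_mode="shrink", data_stage="F",
                               source=corrupted, max_epochs=3, lr=0.003, seed=5)
        obj = build_alpha_objective(corrupted, small_bundle, spec)
        assert obj(0.12) < obj(1.0)

    def test_objective_retains_best_weights(self, small_bundle, small_backbone,
                                            trained_pair):
        source = trained_pair[0]["weights"]
        spec = TrainingRunSpec(backbone=small_backbone, init_mode="shrink", data_stage="F",
                               source=source, max_epochs=1, seed=5)
        obj = build_alpha_objective(source, small_bundle, spec)
        l1, l2 = obj(0.3), obj(0.7)
        assert obj.best_loss == pytest.approx(min(l1, l2))
        assert obj.best_weights is not None
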