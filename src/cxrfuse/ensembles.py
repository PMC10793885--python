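"""Weight-level fusion of homologous trained models.

Rather than averaging predictions, these ensembles merge the parameter
tensors of models that share one architecture: Equal Weight Averaging
(EWA) takes the per-layer arithmetic mean, and F-SLSQP searches the
probability simplex for per-model mixing coefficients that minimize

    error = 1 - F_validation(merged model)

by SLSQP with the sum-to-one equality constraint and [0, 1] bounds,
restarted from many random simplex points.  The F-score of a candidate
is computed at that candidate's own validation-F-maximizing threshold.

A diagnostic Earth Mover (Wasserstein-1) distance between the flattened
weight distributions of two models quantifies how similar two
checkpoints are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import wasserstein_distance

from .metrics import PredictionSet, confusion_from_scores, select_threshold_max_f
from .nn import SmallConvNet, WeightCollection
from .synthetic import DatasetBundle

logger = logging.getLogger(__name__)

__all__ = [
    "MixingCoefficients",
    "EnsembleFitResult",
    "weighted_average_weights",
    "ewa_ensemble",
    "f_slsqp_ensemble",
    "weight_emd",
    "emd_matrix",
]


@dataclass(frozen=True)
class MixingCoefficients:
    """Simplex-constrained per-model scaling factors."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if any(v < -1e-12 or v > 1 + 1e-12 for v in vals):
            raise ValueError("coefficients must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("coefficients must sum to 1")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


@dataclass(frozen=True)
class EnsembleFitResult:
    coefficients: MixingCoefficients
    error: float  # 1 - validation F of the merged model
    n_restarts_run: int
    restart_errors: tuple[float, ...]


def _check_mergeable(models: list[WeightCollection]) -> None:
    if len(models) < 2:
        raise ValueError("need at least two models to merge")
    ref = models[0].fingerprint
    for k, m in enumerate(models[1:], start=1):
        if m.fingerprint != ref:
            for (na, sa), (nb, sb) in zip(ref, m.fingerprint):
                if (na, sa) != (nb, sb):
                    raise ValueError(
                        f"model {k} not mergeable: layer {nb!r} has shape {sb}, expected {na!r} {sa}"
                    )
            raise ValueError(f"model {k} not mergeable with model 0")


def weighted_average_weights(
    models: list[WeightCollection], coeffs: MixingCoefficients
) -> WeightCollection:
    """Per-layer convex combination: out = sum_i c_i * W_i."""
    _check_mergeable(models)
    if len(coeffs) != len(models):
        raise ValueError(f"{len(coeffs)} coefficients for {len(models)} models")
    items = []
    for j, (name, _) in enumerate(models[0]):
        merged = sum(c * m.items[j][1] for c, m in zip(coeffs, models))
        items.append((name, merged))
    return WeightCollection(tuple(items))


def ewa_ensemble(models: list[WeightCollection]) -> WeightCollection:
    """Equal Weight Averaging: arithmetic mean of every layer."""
    k = len(models)
    return weighted_average_weights(models, MixingCoefficients((1.0 / k,) * k))


def _validation_xy(validation, stage: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(validation, DatasetBundle):
        _, val_key = validation.stage_train_val(stage)
        return validation.split(val_key)
    x, y = validation
    return np.asarray(x), np.asarray(y)


def merged_error(
    coeffs: MixingCoefficients,
    models: list[WeightCollection],
    template: SmallConvNet,
    x_val: np.ndarray,
    y_val: np.ndarray,
) -> float:
    """Eq-style objective: 1 - validation F of the merged model at its
    own max-F threshold."""
    template.set_weights(weighted_average_weights(models, coeffs))
    preds = PredictionSet(scores=template.predict_scores(x_val), labels=y_val)
    t = select_threshold_max_f(preds)
    c = confusion_from_scores(preds, t)
    p = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return 1.0 - f


def f_slsqp_ensemble(
    models: list[WeightCollection],
    template: SmallConvNet,
    validation: DatasetBundle | tuple[np.ndarray, np.ndarray],
    n_restarts: int = 100,
    seed: int = 0,
    stage: str = "F",
) -> tuple[EnsembleFitResult, WeightCollection]:
    """Find simplex mixing coefficients minimizing 1 - validation F.

    SLSQP runs from ``n_restarts`` starting points — the equal-weights
    point first, then uniform draws from the simplex — under the
    sum-to-one equality constraint and [0, 1] bounds.  The global best
    over *every* objective evaluation is kept, so the result can never
    be worse than equal weight averaging.
    """
    _check_mergeable(models)
    x_val, y_val = _validation_xy(validation, stage)
    if y_val.min() == y_val.max():
        raise ValueError("validation split must contain both classes")
    k = len(models)
    rng = np.random.default_rng(seed)

    cache: dict[tuple, float] = {}
    best: dict = {"err": np.inf, "coeffs": None}

    def objective(v: np.ndarray) -> float:
        v = np.clip(v, 0.0, 1.0)
        s = v.sum()
        v = v / s if s > 0 else np.full(k, 1.0 / k)
        key = tuple(np.round(v, 6))
        if key not in cache:
            cache[key] = merged_error(
                MixingCoefficients(tuple(v)), models, template, x_val, y_val
            )
        err = cache[key]
        if err < best["err"]:
            best["err"], best["coeffs"] = err, tuple(v)
        return err

    starts = [np.full(k, 1.0 / k)] + [rng.dirichlet(np.ones(k)) for _ in range(n_restarts - 1)]
    restart_errors, failures = [], []
    for x0 in starts[:n_restarts]:
        res = minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * k,
            constraints=[{"type": "eq", "fun": lambda v: v.sum() - 1.0}],
            options={"maxiter": 50, "ftol": 1e-9},
        )
        restart_errors.append(float(res.fun))
        if not res.success:
            failures.append(res.message)
    if best["coeffs"] is None:
        raise RuntimeError(f"SLSQP failed on every restart: {failures}")

    coeffs = MixingCoefficients(best["coeffs"])
    merged = weighted_average_weights(models, coeffs)
    logger.info(
        "F-SLSQP: error %.4f with coefficients %s over %d restarts (%d cache entries)",
        best["err"], np.round(coeffs.values, 4), len(restart_errors), len(cache),
    )
    return (
        EnsembleFitResult(
            coefficients=coeffs,
            error=float(best["err"]),
            n_restarts_run=len(restart_errors),
            restart_errors=tuple(restart_errors),
        ),
        merged,
    )


def weight_emd(a: WeightCollection, b: WeightCollection) -> float:
    """Wasserstein-1 distance between the flattened weight distributions."""
    _check_mergeable([a, b])
    return float(wasserstein_distance(a.flatten(), b.flatten()))


def emd_matrix(collections: dict[str, WeightCollection]) -> pd.DataFrame:
    """Square, labeled EMD matrix (for heatmap rendering / CSV export)."""
    names = list(collections)
    mat = np.zeros((len(names), len(names)))
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if j > i:
                mat[i, j] = mat[j, i] = weight_emd(collections[ni], collections[nj])
    return pd.DataFrame(mat, index=names, columns=names)
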