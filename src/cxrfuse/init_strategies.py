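"""Cold-start, warm-start and shrink-and-perturb re-initialization.

Shrink-and-perturb rescales an existing checkpoint's weights toward zero
and perturbs them, W' = alpha * W + noise, before continued training on
newly arrived data; the scaling factor alpha is found by Gaussian-process
Bayesian optimization of the resulting best validation loss over the
interval [0.1, 0.9].  The training driver checkpoints at the epoch of
lowest validation loss.

``noise_mode="gaussian"`` (default) draws i.i.d. zero-mean Gaussian noise
with standard deviation beta, following the original shrink-and-perturb
recipe; ``noise_mode="constant"`` adds the literal scalar beta to every
weight instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from scipy import stats

from .nn import Adam, SmallConvNet, WeightCollection, softmax_cross_entropy
from .synthetic import BackboneSpec, DatasetBundle, make_backbone

logger = logging.getLogger(__name__)

__all__ = [
    "ShrinkPerturbConfig",
    "AlphaSearchConfig",
    "TrainingRunSpec",
    "shrink_perturb_weights",
    "gp_optimize_alpha",
    "train_model",
    "build_alpha_objective",
]


@dataclass(frozen=True)
class ShrinkPerturbConfig:
    alpha: float
    beta: float = 0.01
    noise_mode: str = "gaussian"  # or "constant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.noise_mode not in ("gaussian", "constant"):
            raise ValueError("noise_mode must be 'gaussian' or 'constant'")


@dataclass(frozen=True)
class AlphaSearchConfig:
    bounds: tuple[float, float] = (0.1, 0.9)
    n_calls: int = 100
    n_random_starts: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random_starts > self.n_calls:
            raise ValueError("n_random_starts cannot exceed n_calls")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("invalid bounds")


@dataclass(frozen=True)
class TrainingRunSpec:
    """One training run: how to initialize and what to train on.

    ``init_mode``: 'cold-R' (random), 'cold-I' (pretrained source
    weights), 'warm' (continue from checkpoint), 'shrink'
    (shrink-and-perturb the checkpoint).  Warm, shrink and cold-I need a
    ``source`` checkpoint.
    """

    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    init_mode: str = "cold-R"
    data_stage: str = "F"
    source: WeightCollection | None = None
    alpha: float = 0.5
    beta: float = 0.01
    noise_mode: str = "gaussian"
    lr: float = 0.001
    batch_size: int = 32
    max_epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.init_mode not in ("cold-R", "cold-I", "warm", "shrink"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.init_mode in ("cold-I", "warm", "shrink") and self.source is None:
            raise ValueError(f"init_mode {self.init_mode!r} requires a source checkpoint")
        if self.data_stage not in ("P", "F"):
            raise ValueError("data_stage must be 'P' or 'F'")


def shrink_perturb_weights(w: WeightCollection, cfg: ShrinkPerturbConfig) -> WeightCollection:
    """W' = alpha * W + noise for every tensor; shapes unchanged."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_mode == "constant":
        return w.map(lambda name, t: cfg.alpha * t + cfg.beta)
    return w.map(lambda name, t: cfg.alpha * t + rng.normal(0.0, cfg.beta, size=t.shape))


# ---------------------------------------------------------------------------
# GP Bayesian optimization of alpha


def _expected_improvement(mu: np.ndarray, sd: np.ndarray, best: float) -> np.ndarray:
    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return (best - mu) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)


def gp_optimize_alpha(
    objective: Callable[[float], float], search: AlphaSearchConfig
) -> tuple[float, list[tuple[float, float]]]:
    """Minimize a scalar objective over the alpha bounds by GP search.

    Starts with ``n_random_starts`` uniform draws, then proposes each
    next point by maximizing expected improvement under a Matern-5/2
    Gaussian process fit to the evaluations so far.  Returns the argmin
    over every evaluated point and the full (alpha, loss) history of
    length ``n_calls``.
    """
    rng = np.random.default_rng(search.seed)
    lo, hi = search.bounds
    history: list[tuple[float, float]] = []

    def _eval(a: float) -> None:
        a = float(np.clip(a, lo, hi))
        try:
            history.append((a, float(objective(a))))
        except Exception as exc:  # annotate which alpha failed
            raise RuntimeError(f"alpha objective failed at alpha={a:.6f}") from exc

    for _ in range(search.n_random_starts):
        _eval(rng.uniform(lo, hi))

    while len(history) < search.n_calls:
        xs = np.array([[a] for a, _ in history])
        ys = np.array([l for _, l in history])
        spread = ys.std() or 1.0
        gp = GaussianProcessRegressor(
            kernel=Matern(
                length_scale=0.2 * (hi - lo),
                length_scale_bounds=(0.01 * (hi - lo), 10.0 * (hi - lo)),
                nu=2.5,
            ),
            alpha=1e-6 * spread**2 + 1e-10,
            normalize_y=True,
        )
        gp.fit(xs, ys)
        cand = np.concatenate([rng.uniform(lo, hi, 256), np.linspace(lo, hi, 65)])
        mu, sd = gp.predict(cand[:, None], return_std=True)
        _eval(cand[int(np.argmax(_expected_improvement(mu, sd, ys.min())))])

    best_alpha, _ = min(history, key=lambda al: al[1])
    return best_alpha, history


# ---------------------------------------------------------------------------
# Training driver


def _initial_weights(spec: TrainingRunSpec, model: SmallConvNet) -> None:
    if spec.init_mode == "cold-R":
        model.init_weights(spec.seed)
    elif spec.init_mode == "cold-I":
        # pretrained backbone with a freshly initialized task head, the way
        # a natural-image-pretrained backbone is fitted with a new 2-unit
        # dense layer for the target task; the head starts at zero so the
        # initial predictions are the class prior rather than noise
        model.init_weights(spec.seed)
        fresh = model.get_weights()
        items = tuple(
            (n, np.zeros_like(t) if n.startswith("head.") else spec.source.get(n))
            for n, t in fresh
        )
        model.set_weights(WeightCollection(items))
    elif spec.init_mode == "warm":
        model.set_weights(spec.source)
    else:  # shrink
        cfg = ShrinkPerturbConfig(
            alpha=spec.alpha, beta=spec.beta, noise_mode=spec.noise_mode, seed=spec.seed
        )
        model.set_weights(shrink_perturb_weights(spec.source, cfg))


def train_model(
    spec: TrainingRunSpec, data: DatasetBundle
) -> tuple[WeightCollection, list[dict], float]:
    """Train on the spec's data stage; return the lowest-val-loss snapshot.

    ``history`` holds one record per epoch (epoch 0 is the untrained
    initialization) with train and validation loss; the returned weights
    are the snapshot at the minimum validation loss over the whole
    history, not the final epoch.
    """
    train_key, val_key = data.stage_train_val(spec.data_stage)
    x_tr, y_tr = data.split(train_key)
    x_va, y_va = data.split(val_key)

    model = SmallConvNet(spec.backbone.image_size, spec.backbone.channels)
    _initial_weights(spec, model)

    rng = np.random.default_rng(spec.seed + 104729)  # decoupled from init draws
    opt = Adam(lr=spec.lr)
    best_weights = model.get_weights()
    best_val = model.loss_on(x_va, y_va)
    history: list[dict] = [
        {"epoch": 0, "train_loss": model.loss_on(x_tr, y_tr), "val_loss": best_val}
    ]
    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(len(x_tr))
        running, seen = 0.0, 0
        for i in range(0, len(x_tr), spec.batch_size):
            idx = order[i : i + spec.batch_size]
            loss, grad = softmax_cross_entropy(model.logits(x_tr[idx]), y_tr[idx])
            model.backward(grad)
            model.apply_param_update(opt.step(model.params(), model.grads()))
            running += loss * len(idx)
            seen += len(idx)
        val_loss = model.loss_on(x_va, y_va)
        history.append({"epoch": epoch, "train_loss": running / seen, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
    logger.info(
        "trained %s/%s: best val loss %.4f at epoch %d",
        spec.init_mode, spec.data_stage, best_val,
        int(np.argmin([h["val_loss"] for h in history])),
    )
    return best_weights, history, best_val


class _AlphaObjective:
    """alpha -> best validation loss of a shrink-initialized training run.

    Retains the best (loss, alpha, weights) seen across calls so the
    winning model does not need retraining.
    """

    def __init__(self, source: WeightCollection, data: DatasetBundle, spec: TrainingRunSpec):
        self.source, self.data = source, data
        self.spec = replace(spec, init_mode="shrink", source=source)
        self.best_loss = np.inf
        self.best_alpha: float | None = None
        self.best_weights: WeightCollection | None = None
        self.best_history: list[dict] | None = None

    def __call__(self, alpha: float) -> float:
        weights, history, best_val = train_model(replace(self.spec, alpha=float(alpha)), self.data)
        if best_val < self.best_loss:
            self.best_loss = best_val
            self.best_alpha = float(alpha)
            self.best_weights = weights
            self.best_history = history
        return best_val


def build_alpha_objective(
    source: WeightCollection, data: DatasetBundle, spec: TrainingRunSpec
) -> _AlphaObjective:
    """Objective for :func:`gp_optimize_alpha` over shrink factors."""
    return _AlphaObjective(source, data, spec)
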