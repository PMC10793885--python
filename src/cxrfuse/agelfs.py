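"""Attention-guided ensemble with a learnable fuzzy softmax head (AGELFS).

Frozen constituent classifiers each emit a global-average-pooled feature
vector; the vectors are concatenated, reweighted feature-wise by a
learned attention gate, and classified by a dense two-unit head whose
output passes through a *learnable fuzzy softmax*

    LFS(x)_i = exp(f * x_i) / sum_j exp(f * x_j)

— a temperature-scaled softmax whose multiplier ``f`` (the fuzziness) is
itself trained.  Only the attention gate, the head and the fuzziness are
trainable; constituent parameters are bit-identical before and after
ensemble training.

The fuzziness is kept positive through a softplus reparameterization and
initialized at 1.0 (where the LFS is the conventional softmax).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .nn import Adam, SmallConvNet, WeightCollection, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "AGELFSSpec",
    "AGELFSEnsemble",
    "learnable_fuzzy_softmax",
    "build_agelfs",
    "train_agelfs",
]

_RHO_FOR_UNIT_FUZZINESS = math.log(math.e - 1.0)  # softplus(rho) == 1


def learnable_fuzzy_softmax(logits: np.ndarray, fuzziness: float) -> np.ndarray:
    """Temperature-scaled softmax with multiplier ``fuzziness``.

    Works on a single vector or a batch (softmax over the last axis);
    numerically stabilized by max-subtraction.  ``fuzziness = 1`` is the
    conventional softmax; ``fuzziness -> 0`` flattens the output toward
    uniform and ``fuzziness -> inf`` sharpens it toward the argmax.
    """
    if fuzziness < 0:
        raise ValueError("fuzziness must be non-negative")
    z = np.asarray(logits, dtype=float)
    if not np.isfinite(z).any(axis=-1).all():
        raise ValueError("logits contain no finite entry")
    return softmax(fuzziness * z, axis=-1)


@dataclass(frozen=True)
class AGELFSSpec:
    attention_variant: str = "gating"  # learned softmax gate over features
    lfs_input: str = "logits"  # or "probabilities": softmax-then-LFS
    head_init: str = "random"  # or "zeros"
    lr: float = 0.001
    batch_size: int = 32
    max_epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attention_variant not in ("gating",):
            raise ValueError(f"unsupported attention variant {self.attention_variant!r}")
        if self.lfs_input not in ("logits", "probabilities"):
            raise ValueError("lfs_input must be 'logits' or 'probabilities'")


class AGELFSEnsemble:
    """Frozen constituents -> GAP features -> attention gate -> dense(2) -> LFS."""

    def __init__(self, spec: AGELFSSpec, models: list[SmallConvNet]):
        if len(models) < 2:
            raise ValueError("need at least two constituent models")
        sizes = {m.image_size for m in models}
        if len(sizes) > 1:
            raise ValueError(f"constituents accept different input sizes: {sorted(sizes)}")
        self.spec = spec
        self.models = models
        self.feature_width = sum(m.feature_width for m in models)
        d = self.feature_width
        rng = np.random.default_rng(spec.seed)
        if spec.head_init == "zeros":
            self.Wa = np.zeros((d, d))
            self.Wh = np.zeros((d, 2))
        else:
            self.Wa = rng.normal(0.0, 1.0 / np.sqrt(d), (d, d))
            self.Wh = rng.normal(0.0, 1.0 / np.sqrt(d), (d, 2))
        self.ba = np.zeros(d)
        self.bh = np.zeros(2)
        self.rho = _RHO_FOR_UNIT_FUZZINESS
        self._frozen_hash = self.constituent_hash()

    # -- bookkeeping --------------------------------------------------------
    @property
    def fuzziness(self) -> float:
        return float(np.logaddexp(0.0, self.rho))  # softplus

    def constituent_hash(self) -> int:
        h = 0
        for m in self.models:
            h ^= m.get_weights().content_hash()
        return h

    def trainable_parameter_count(self) -> int:
        return self.Wa.size + self.ba.size + self.Wh.size + self.bh.size + 1

    def trainable_state(self) -> dict[str, np.ndarray | float]:
        return {
            "Wa": self.Wa.copy(), "ba": self.ba.copy(),
            "Wh": self.Wh.copy(), "bh": self.bh.copy(), "rho": self.rho,
        }

    def load_trainable_state(self, state: dict) -> None:
        self.Wa = np.array(state["Wa"], dtype=float)
        self.ba = np.array(state["ba"], dtype=float)
        self.Wh = np.array(state["Wh"], dtype=float)
        self.bh = np.array(state["bh"], dtype=float)
        self.rho = float(state["rho"])

    def sidecar(self) -> dict:
        return {
            "method": "agelfs",
            "attention_variant": self.spec.attention_variant,
            "lfs_input": self.spec.lfs_input,
            "fuzziness": self.fuzziness,
            "n_constituents": len(self.models),
        }

    # -- forward ------------------------------------------------------------
    def features(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([m.features(x) for m in self.models], axis=1)

    def _head(self, feats: np.ndarray) -> dict[str, np.ndarray]:
        a = softmax(feats @ self.Wa + self.ba, axis=1)
        g = feats * a
        z = g @ self.Wh + self.bh
        f = self.fuzziness
        if self.spec.lfs_input == "probabilities":
            s = softmax(z, axis=1)
            p = softmax(f * s, axis=1)
            return {"a": a, "g": g, "z": z, "s": s, "p": p}
        return {"a": a, "g": g, "z": z, "p": softmax(f * z, axis=1)}

    def predict_proba_from_features(self, feats: np.ndarray) -> np.ndarray:
        return self._head(feats)["p"]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba_from_features(self.features(x))

    def predict_scores(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = [
            self.predict_proba(x[i : i + batch_size])[:, 1]
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out)

    # -- one gradient step on precomputed features --------------------------
    def loss_and_grads(
        self, feats: np.ndarray, labels: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray | float]]:
        n = feats.shape[0]
        c = self._head(feats)
        p, z, g, a = c["p"], c["z"], c["g"], c["a"]
        loss = float(-np.log(p[np.arange(n), labels] + 1e-12).mean())
        G = p.copy()
        G[np.arange(n), labels] -= 1.0
        G /= n  # dL/d(LFS pre-activation)
        f = self.fuzziness
        if self.spec.lfs_input == "probabilities":
            s = c["s"]
            df = float(np.sum(G * s))
            ds = f * G
            dz = s * (ds - np.sum(ds * s, axis=1, keepdims=True))
        else:
            df = float(np.sum(G * z))
            dz = f * G
        dWh = g.T @ dz
        dbh = dz.sum(axis=0)
        dg = dz @ self.Wh.T
        da = dg * feats
        du = a * (da - np.sum(da * a, axis=1, keepdims=True))
        dWa = feats.T @ du
        dba = du.sum(axis=0)
        drho = df / (1.0 + math.exp(-self.rho))  # d softplus / d rho = sigmoid
        return loss, {"Wa": dWa, "ba": dba, "Wh": dWh, "bh": dbh, "rho": drho}


def build_agelfs(spec: AGELFSSpec, models: list[SmallConvNet]) -> AGELFSEnsemble:
    """Assemble the ensemble graph over frozen constituents."""
    return AGELFSEnsemble(spec, models)


def train_agelfs(
    ensemble: AGELFSEnsemble,
    data,
    stage: str = "F",
) -> tuple[AGELFSEnsemble, float, list[dict]]:
    """Train the unfrozen head on the bundle's train split of ``stage``.

    Constituent features are computed once (the constituents are frozen,
    so they never change), then the attention gate, dense head and
    fuzziness are fit with Adam and cross-entropy, checkpointing the
    trainable state at the lowest validation loss.  Returns the ensemble
    with the best state loaded, the learned fuzziness, and the history.
    """
    spec = ensemble.spec
    train_key, val_key = data.stage_train_val(stage)
    x_tr, y_tr = data.split(train_key)
    x_va, y_va = data.split(val_key)
    f_tr = ensemble.features(x_tr)
    f_va = ensemble.features(x_va)

    def val_loss() -> float:
        p = ensemble.predict_proba_from_features(f_va)
        return float(-np.log(p[np.arange(len(y_va)), y_va] + 1e-12).mean())

    rng = np.random.default_rng(spec.seed + 7919)
    opt = Adam(lr=spec.lr)
    best_state, best_val = ensemble.trainable_state(), val_loss()
    history = [{"epoch": 0, "train_loss": float("nan"), "val_loss": best_val}]
    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(len(f_tr))
        running, seen = 0.0, 0
        for i in range(0, len(f_tr), spec.batch_size):
            idx = order[i : i + spec.batch_size]
            loss, grads = ensemble.loss_and_grads(f_tr[idx], y_tr[idx])
            params = {
                "Wa": ensemble.Wa, "ba": ensemble.ba,
                "Wh": ensemble.Wh, "bh": ensemble.bh,
                "rho": np.array([ensemble.rho]),
            }
            grads["rho"] = np.array([grads["rho"]])
            new = opt.step(params, grads)
            ensemble.Wa, ensemble.ba = new["Wa"], new["ba"]
            ensemble.Wh, ensemble.bh = new["Wh"], new["bh"]
            ensemble.rho = float(new["rho"][0])
            running += loss * len(idx)
            seen += len(idx)
        vl = val_loss()
        history.append({"epoch": epoch, "train_loss": running / seen, "val_loss": vl})
        if vl < best_val:
            best_val, best_state = vl, ensemble.trainable_state()
    ensemble.load_trainable_state(best_state)
    if ensemble.constituent_hash() != ensemble._frozen_hash:
        raise RuntimeError("constituent parameters changed during ensemble training")
    logger.info("AGELFS trained: fuzziness %.4f, best val loss %.4f", ensemble.fuzziness, best_val)
    return ensemble, ensemble.fuzziness, history
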