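"""Checkpoint and prediction persistence.

Weights are stored as an ``.npz`` of named arrays with a JSON sidecar
carrying the ordered layer-name manifest (so collections stay portable)
plus any run metadata (history, alpha, coefficients, fuzziness).
Predictions travel as CSV with columns sample_id, score, label, split.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import WeightCollection

__all__ = ["save_weights", "load_weights", "save_predictions", "load_predictions"]


def save_weights(path: str | Path, weights: WeightCollection, meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **{name: tensor for name, tensor in weights})
    sidecar = {"layers": list(weights.names)}
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=float))
    return path


def load_weights(path: str | Path) -> tuple[WeightCollection, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as data:
        items = tuple((name, data[name]) for name in sidecar["layers"])
    return WeightCollection(items), sidecar


def save_predictions(path: str | Path, frames: list[pd.DataFrame]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def load_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
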