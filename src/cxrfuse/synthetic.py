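"""Desk-scale synthetic two-class image data emulating a CXR study design.

Generates grayscale images in [0, 1] for a binary abnormal-vs-no-finding
task with the structural features of the real study this package's
pipeline is meant for:

* ~1:2 no-finding:abnormal class imbalance at the patient level,
* patient-level 70/10/20 train/validation/test split,
* halving of train and validation into a "P" (partial) and "F" (full)
  stage to simulate periodic data arrival, with the internal test shared
  by both stages,
* covariate-shifted external test sets (intensity offset, contrast
  compression, lesion blurring) standing in for adult and pediatric
  external cohorts of increasing severity,
* a source-task pretraining stand-in for large-scale natural-image
  pretraining.

Abnormal images carry bright Gaussian-blob opacities whose amplitude is
the ``class_separation`` effect size; normal images share the same
smooth background process.  Everything is deterministic under the spec
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy import ndimage

from .nn import SmallConvNet, Adam, softmax_cross_entropy, WeightCollection

__all__ = [
    "ShiftParams",
    "SyntheticDatasetSpec",
    "DatasetBundle",
    "BackboneSpec",
    "generate_dataset",
    "generate_external_shift",
    "make_backbone",
    "pretrain_source_task",
    "export_dataset",
    "DEFAULT_EXTERNAL_SHIFTS",
    "cxr_mini_spec",
]


@dataclass(frozen=True)
class ShiftParams:
    """Covariate shift applied to test images (labels unchanged).

    ``intensity_offset`` shifts the brightness, ``contrast_scale``
    compresses the dynamic range around mid-gray, ``blur_sigma`` smooths
    the image (degrading lesion morphology the way a population change
    degrades a fixed model), and ``noise_sigma`` adds fresh acquisition
    noise after the blur.  The all-default parameters are the identity.
    """

    intensity_offset: float = 0.0
    contrast_scale: float = 1.0
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0


# Severity ordering mirrors the external cohorts: the adult shift is
# mildest; the three pediatric strata shift progressively harder (younger
# lungs look less like the adult training distribution).
DEFAULT_EXTERNAL_SHIFTS: dict[str, ShiftParams] = {
    "adult": ShiftParams(0.04, 0.90, 0.5, 0.03),
    "ped18": ShiftParams(0.08, 0.78, 0.9, 0.04),
    "ped11": ShiftParams(0.12, 0.65, 1.4, 0.05),
    "ped2": ShiftParams(0.18, 0.50, 2.0, 0.06),
}


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    n_patients: int = 300
    images_per_patient: int = 1
    image_size: int = 64
    abnormal_fraction: float = 0.67
    class_separation: float = 1.0
    external_shifts: dict[str, ShiftParams] = field(
        default_factory=lambda: dict(DEFAULT_EXTERNAL_SHIFTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.abnormal_fraction < 1.0:
            raise ValueError("abnormal_fraction must lie in (0, 1)")
        if self.n_patients <= 0 or self.images_per_patient <= 0 or self.image_size <= 0:
            raise ValueError("all counts must be positive")


@dataclass
class DatasetBundle:
    """Images, labels and patient ids organized into the study splits.

    Split keys: ``train_P``, ``val_P``, ``train_F``, ``val_F``, ``test``
    plus one ``external_<name>`` entry per configured shift.  The P-stage
    train/val are prefixes of the F-stage ones; the internal test is
    shared by both stages.
    """

    images: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    patients: dict[str, np.ndarray]
    spec: SyntheticDatasetSpec

    def split(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        return self.images[name], self.labels[name]

    def stage_train_val(self, stage: str) -> tuple[str, str]:
        if stage not in ("P", "F"):
            raise ValueError("stage must be 'P' or 'F'")
        return f"train_{stage}", f"val_{stage}"

    @property
    def external_names(self) -> tuple[str, ...]:
        return tuple(
            k.removeprefix("external_") for k in self.images if k.startswith("external_")
        )


def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, (size, size))
    f = ndimage.gaussian_filter(noise, sigma)
    s = f.std()
    return f / s if s > 0 else f


def _render_image(
    rng: np.random.Generator, size: int, abnormal: bool, separation: float,
    patient_offset: float,
) -> np.ndarray:
    # background varies at a much larger spatial scale than the lesions so
    # the two are separable by shape, not by brightness alone
    img = 0.40 + patient_offset
    img = img + 0.08 * _smooth_field(rng, size, sigma=size / 4)
    img = img + 0.03 * rng.normal(0.0, 1.0, (size, size))
    if abnormal and separation > 0:
        n_blobs = rng.integers(2, 5)
        yy, xx = np.mgrid[0:size, 0:size]
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0.2 * size, 0.8 * size, size=2)
            s = rng.uniform(0.06 * size, 0.10 * size)
            amp = 0.45 * separation * rng.uniform(0.8, 1.2)
            img = img + amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s)))
    elif abnormal:
        # zero effect size: still consume the same random draws so the
        # background is identical in distribution to the normal class
        rng.integers(2, 5)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: SyntheticDatasetSpec) -> DatasetBundle:
    """Generate the full bundle (internal splits + configured externals)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    n_abn = int(round(spec.abnormal_fraction * n))
    patient_labels = np.zeros(n, dtype=int)
    patient_labels[rng.permutation(n)[:n_abn]] = 1

    n_test = int(round(0.2 * n))
    n_val = int(round(0.1 * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"cannot form a 70/10/20 patient split from {n} patients")
    order = rng.permutation(n)
    assign = {"train": order[:n_train], "val": order[n_train : n_train + n_val],
              "test": order[n_train + n_val :]}

    per_patient_offset = rng.normal(0.0, 0.05, size=n)

    def _render_split(patient_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        imgs, labs, pids = [], [], []
        for p in patient_idx:
            for _ in range(spec.images_per_patient):
                imgs.append(
                    _render_image(
                        rng, spec.image_size, bool(patient_labels[p]),
                        spec.class_separation, per_patient_offset[p],
                    )
                )
                labs.append(patient_labels[p])
                pids.append(p)
        return np.array(imgs), np.array(labs, dtype=int), np.array(pids, dtype=int)

    images: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    patients: dict[str, np.ndarray] = {}
    for split, idx in assign.items():
        key = "test" if split == "test" else f"{split}_F"
        images[key], labels[key], patients[key] = _render_split(idx)

    # P stage: first half (per-image prefix; patients stay inside 'train'/'val')
    for split in ("train", "val"):
        full = f"{split}_F"
        half = math.ceil(len(images[full]) / 2)
        part = f"{split}_P"
        images[part] = images[full][:half]
        labels[part] = labels[full][:half]
        patients[part] = patients[full][:half]

    bundle = DatasetBundle(images=images, labels=labels, patients=patients, spec=spec)
    for name, shift in spec.external_shifts.items():
        x, y, p = generate_external_shift(bundle, shift, seed=spec.seed + 1)
        bundle.images[f"external_{name}"] = x
        bundle.labels[f"external_{name}"] = y
        bundle.patients[f"external_{name}"] = p
    return bundle


def generate_external_shift(
    bundle: DatasetBundle, shift: ShiftParams, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Covariate-shifted copy of the internal test split.

    Label semantics are unchanged; only the image appearance moves.  The
    transform is deterministic given the pixels, ``shift`` and ``seed``
    (which drives the fresh acquisition noise), so a zero shift returns
    bit-identical images.
    """
    x, y = bundle.split("test")
    out = x.copy()
    if shift.blur_sigma > 0:
        out = np.stack([ndimage.gaussian_filter(im, shift.blur_sigma) for im in out])
    if shift.contrast_scale != 1.0 or shift.intensity_offset != 0.0:
        out = shift.contrast_scale * (out - 0.5) + 0.5 + shift.intensity_offset
    if shift.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, shift.noise_sigma, size=out.shape)
    if shift == ShiftParams():
        return out, y.copy(), bundle.patients["test"].copy()
    return np.clip(out, 0.0, 1.0), y.copy(), bundle.patients["test"].copy()


# ---------------------------------------------------------------------------
# Backbones


@dataclass(frozen=True)
class BackboneSpec:
    """Tiny conv backbone: conv blocks ending at the deepest pooling
    layer, then GAP and a dense 2-unit softmax head."""

    image_size: int = 64
    channels: tuple[int, ...] = (8, 16, 32)


def make_backbone(spec: BackboneSpec, seed: int = 0) -> SmallConvNet:
    model = SmallConvNet(spec.image_size, spec.channels)
    model.init_weights(seed)
    return model


# ---------------------------------------------------------------------------
# Source-task pretraining (stand-in for natural-image pretraining)


def _source_task_data(
    rng: np.random.Generator, size: int, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Auxiliary task: oriented gratings (class 0) vs soft bright bumps
    (class 1).

    A different classification problem from the target (no shared
    backgrounds, different class semantics), but its solution requires
    blob- and edge-sensitive filters at scales comparable to the
    target's lesions — the feature reuse that natural-image pretraining
    provides at full scale."""
    imgs = np.zeros((n, size, size))
    labs = rng.integers(0, 2, size=n)
    yy, xx = np.mgrid[0:size, 0:size]
    for i in range(n):
        base = 0.4 + 0.08 * _smooth_field(rng, size, sigma=size / 4)
        base = base + 0.04 * rng.normal(0.0, 1.0, (size, size))
        if labs[i] == 0:
            freq = rng.uniform(0.2, 0.6)
            phase = rng.uniform(0, 2 * np.pi)
            axis = yy if rng.random() < 0.5 else xx
            base = base + 0.25 * np.sin(freq * axis + phase)
        else:
            for _ in range(rng.integers(2, 5)):
                cy, cx = rng.uniform(0.1 * size, 0.9 * size, size=2)
                s = rng.uniform(0.06 * size, 0.10 * size)
                base = base + 0.45 * np.exp(
                    -(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))
                )
        imgs[i] = np.clip(base, 0.0, 1.0)
    return imgs, labs


def pretrain_source_task(
    backbone: BackboneSpec | SmallConvNet,
    seed: int = 0,
    n_images: int = 256,
    epochs: int = 8,
    batch_size: int = 16,
    lr: float = 0.003,
) -> WeightCollection:
    """Train the backbone on the auxiliary source task; return its weights."""
    model = make_backbone(backbone, seed=seed) if isinstance(backbone, BackboneSpec) else backbone
    rng = np.random.default_rng(seed)
    x, y = _source_task_data(rng, model.image_size, n_images)
    opt = Adam(lr=lr)
    for _ in range(epochs):
        order = rng.permutation(len(x))
        for i in range(0, len(x), batch_size):
            idx = order[i : i + batch_size]
            loss, grad = softmax_cross_entropy(model.logits(x[idx]), y[idx])
            model.backward(grad)
            model.apply_param_update(opt.step(model.params(), model.grads()))
    return model.get_weights()


# ---------------------------------------------------------------------------
# Export


def export_dataset(bundle: DatasetBundle, outdir: str | Path) -> Path:
    """Write the bundle as PNG directories plus a CSV manifest.

    Manifest columns: sample_id, patient_id, label, split.  The spec is
    saved alongside as YAML so the bundle can be regenerated.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for split, imgs in bundle.images.items():
        d = outdir / split
        d.mkdir(exist_ok=True)
        for i, img in enumerate(imgs):
            sid = f"{split}_{i:05d}"
            Image.fromarray((img * 255).astype(np.uint8)).save(d / f"{sid}.png")
            rows.append(
                {
                    "sample_id": sid,
                    "patient_id": int(bundle.patients[split][i]),
                    "label": int(bundle.labels[split][i]),
                    "split": split,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    spec_dict = asdict(bundle.spec)
    spec_dict["external_shifts"] = {
        k: asdict(v) if isinstance(v, ShiftParams) else v
        for k, v in spec_dict["external_shifts"].items()
    }
    (outdir / "spec.yaml").write_text(yaml.safe_dump(spec_dict))
    return outdir


def cxr_mini_spec(seed: int = 0, **overrides) -> SyntheticDatasetSpec:
    """The standard desk-scale fixture: 300 patients, 64x64, 2:1 imbalance."""
    kw = dict(n_patients=300, images_per_patient=1, image_size=64,
              abnormal_fraction=0.67, class_separation=1.0, seed=seed)
    kw.update(overrides)
    return SyntheticDatasetSpec(**kw)
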