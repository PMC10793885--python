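"""The experiment driver: the desk-scale study grid end to end.

``run_experiment`` trains the eight model configurations of the study
terminology (Cold-RP, Cold-IP, Cold-RF, Warm-RF, Shrink-RF, Cold-IF,
Warm-IF, Shrink-IF — R/I for random vs pretrained-source initialization,
P/F for the partial vs full data stage), builds the configured weight
ensembles (EWA, F-SLSQP, AGELFS), evaluates everything on the internal
and external test sets at each model's validation-selected threshold,
computes MCC confidence intervals and all pairwise CI-based Z-tests, and
renders report tables.  Stages are resumable: checkpoints already on
disk are loaded instead of retrained.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .agelfs import AGELFSSpec, build_agelfs, train_agelfs
from .ensembles import emd_matrix, ewa_ensemble, f_slsqp_ensemble
from .init_strategies import (
    AlphaSearchConfig,
    TrainingRunSpec,
    build_alpha_objective,
    gp_optimize_alpha,
    train_model,
)
from .metrics import PredictionSet, evaluate_predictions, select_threshold_max_f
from .nn import SmallConvNet, WeightCollection
from .stats_compare import MetricWithCI, ci_z_test, format_p, mcc_ci
from .synthetic import (
    BackboneSpec,
    ShiftParams,
    SyntheticDatasetSpec,
    generate_dataset,
    make_backbone,
    pretrain_source_task,
    cxr_mini_spec,
)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ResultStore", "run_experiment", "render_tables", "STAGES"]

STAGES = ("simulate", "pretrain", "train", "shrink", "ensemble", "evaluate", "compare", "report")

# init mode, data stage, source checkpoint id ("pretrained" = source task)
MODEL_RECIPES: dict[str, tuple[str, str, str | None]] = {
    "Cold-RP": ("cold-R", "P", None),
    "Cold-IP": ("cold-I", "P", "pretrained"),
    "Cold-RF": ("cold-R", "F", None),
    "Warm-RF": ("warm", "F", "Cold-RP"),
    "Shrink-RF": ("shrink", "F", "Cold-RP"),
    "Cold-IF": ("cold-I", "F", "pretrained"),
    "Warm-IF": ("warm", "F", "Cold-IP"),
    "Shrink-IF": ("shrink", "F", "Cold-IP"),
}

_IF_TRIO = ("Cold-IF", "Warm-IF", "Shrink-IF")


@dataclass(frozen=True)
class ExperimentConfig:
    dataset: SyntheticDatasetSpec = field(default_factory=cxr_mini_spec)
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    models: tuple[str, ...] = tuple(MODEL_RECIPES)
    # (ensemble id, method, constituent ids)
    ensembles: tuple[tuple[str, str, tuple[str, ...]], ...] = (
        ("EWA-IF", "ewa", _IF_TRIO),
        ("FSLSQP-IF", "fslsqp", _IF_TRIO),
        ("AGELFS-IF", "agelfs", _IF_TRIO),
    )
    tests: tuple[str, ...] = ("internal", "adult", "ped18", "ped11", "ped2")
    epochs_p: int = 14
    epochs_f: int = 14
    search_epochs: int = 3
    alpha_search: AlphaSearchConfig = field(
        default_factory=lambda: AlphaSearchConfig(n_calls=6, n_random_starts=3)
    )
    slsqp_restarts: int = 10
    agelfs_epochs: int = 15
    lr: float = 0.003
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        ids = list(self.models) + [e[0] for e in self.ensembles]
        if len(set(ids)) != len(ids):
            raise ValueError("model/ensemble ids must be unique")
        for name in self.models:
            if name not in MODEL_RECIPES:
                raise ValueError(f"unknown model config {name!r}")

    def with_seed(self, seed: int) -> "ExperimentConfig":
        return replace(self, seed=seed, dataset=replace(self.dataset, seed=seed))

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["dataset"]["external_shifts"] = {
            k: asdict(v) if isinstance(v, ShiftParams) else v
            for k, v in d["dataset"]["external_shifts"].items()
        }
        Path(path).write_text(yaml.safe_dump(d, default_flow_style=None))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kw = dict(d)
        if "dataset" in kw:
            ds = dict(kw["dataset"])
            if "external_shifts" in ds:
                ds["external_shifts"] = {
                    k: ShiftParams(**v) if isinstance(v, dict) else v
                    for k, v in ds["external_shifts"].items()
                }
            kw["dataset"] = SyntheticDatasetSpec(**ds)
        if "backbone" in kw:
            bb = dict(kw["backbone"])
            if "channels" in bb:
                bb["channels"] = tuple(bb["channels"])
            kw["backbone"] = BackboneSpec(**bb)
        if "alpha_search" in kw:
            a = dict(kw["alpha_search"])
            if "bounds" in a:
                a["bounds"] = tuple(a["bounds"])
            kw["alpha_search"] = AlphaSearchConfig(**a)
        if "models" in kw:
            kw["models"] = tuple(kw["models"])
        if "tests" in kw:
            kw["tests"] = tuple(kw["tests"])
        if "ensembles" in kw:
            kw["ensembles"] = tuple(
                (e[0], e[1], tuple(e[2])) for e in kw["ensembles"]
            )
        return cls(**kw)


class ResultStore:
    """On-disk store of one experiment: checkpoints, metrics, comparisons."""

    def __init__(self, outdir: str | Path):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.metrics: list[dict] = []
        self.comparisons: list[dict] = []
        self.meta: dict = {}

    # checkpoints -----------------------------------------------------------
    def ckpt_path(self, model_id: str) -> Path:
        return self.outdir / "checkpoints" / f"{model_id}.npz"

    def has_ckpt(self, model_id: str) -> bool:
        return self.ckpt_path(model_id).exists()

    def save_ckpt(self, model_id: str, weights: WeightCollection, meta: dict | None = None) -> None:
        wio.save_weights(self.ckpt_path(model_id), weights, meta)

    def load_ckpt(self, model_id: str) -> tuple[WeightCollection, dict]:
        return wio.load_weights(self.ckpt_path(model_id))

    # results ---------------------------------------------------------------
    @property
    def report_path(self) -> Path:
        return self.outdir / "report.json"

    def save(self) -> None:
        payload = {"meta": self.meta, "metrics": self.metrics, "comparisons": self.comparisons}
        self.report_path.write_text(json.dumps(payload, indent=1, default=float, sort_keys=True))

    def load(self) -> bool:
        if not self.report_path.exists():
            return False
        payload = json.loads(self.report_path.read_text())
        self.meta = payload["meta"]
        self.metrics = payload["metrics"]
        self.comparisons = payload["comparisons"]
        return True

    def log(self, event: str, **fields) -> None:
        rec = {"t": round(time.time(), 3), "event": event, **fields}
        with (self.outdir / "logs.jsonl").open("a") as fh:
            fh.write(json.dumps(rec, default=float) + "\n")
        logger.info("%s %s", event, fields)


def _model_seed(config: ExperimentConfig, model_id: str) -> int:
    offset = list(MODEL_RECIPES).index(model_id) if model_id in MODEL_RECIPES else 97
    return (config.seed * 131 + offset * 7 + 1) % (2**31 - 1)


def _train_one(
    config: ExperimentConfig,
    store: ResultStore,
    model_id: str,
    data,
    sources: dict[str, WeightCollection],
) -> WeightCollection | None:
    init_mode, stage, source_id = MODEL_RECIPES[model_id]
    if store.has_ckpt(model_id):
        store.log("train.skip", model=model_id)
        return store.load_ckpt(model_id)[0]
    source = sources.get(source_id) if source_id else None
    spec = TrainingRunSpec(
        backbone=config.backbone,
        init_mode=init_mode,
        data_stage=stage,
        source=source,
        lr=config.lr,
        batch_size=config.batch_size,
        max_epochs=config.epochs_p if stage == "P" else config.epochs_f,
        seed=_model_seed(config, model_id),
    )
    try:
        if init_mode == "shrink":
            search = replace(config.alpha_search, seed=spec.seed)
            objective = build_alpha_objective(
                source, data, replace(spec, max_epochs=config.search_epochs)
            )
            alpha, history_a = gp_optimize_alpha(objective, search)
            store.log("shrink.search", model=model_id, alpha=alpha,
                      n_calls=len(history_a))
            spec = replace(spec, alpha=alpha)
        t0 = time.time()
        weights, history, best_val = train_model(spec, data)
        meta = {
            "model": model_id, "init_mode": init_mode, "stage": stage,
            "seed": spec.seed, "best_val_loss": best_val, "history": history,
            "train_seconds": round(time.time() - t0, 2),
        }
        if init_mode == "shrink":
            meta["alpha"] = spec.alpha
            meta["alpha_history"] = history_a
        store.save_ckpt(model_id, weights, meta)
        store.log("train.done", model=model_id, best_val_loss=best_val)
        return weights
    except Exception as exc:  # isolate per-model failures
        store.log("train.failed", model=model_id, error=str(exc))
        logger.exception("model %s failed; skipping", model_id)
        return None


def _test_split_key(test: str) -> str:
    return "test" if test == "internal" else f"external_{test}"


def run_experiment(
    config: ExperimentConfig,
    outdir: str | Path,
    until: str = "report",
    force: bool = False,
) -> ResultStore:
    """Run the study grid up to stage ``until`` (resumable)."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; expected one of {STAGES}")
    last = STAGES.index(until)
    store = ResultStore(outdir)
    if force:
        for p in list(store.outdir.rglob("*.npz")) + [store.report_path]:
            p.unlink(missing_ok=True)

    # -- simulate -----------------------------------------------------------
    data = generate_dataset(config.dataset)
    manifest = store.outdir / "manifest.csv"
    if not manifest.exists():
        rows = [
            {"split": k, "n": len(v), "n_abnormal": int(v.sum())}
            for k, v in data.labels.items()
        ]
        pd.DataFrame(rows).to_csv(manifest, index=False)
    store.log("simulate.done", n_patients=config.dataset.n_patients)
    if last < STAGES.index("pretrain"):
        return store

    # -- pretrain -----------------------------------------------------------
    needs_pretrained = any(MODEL_RECIPES[m][2] == "pretrained" for m in config.models)
    sources: dict[str, WeightCollection] = {}
    if needs_pretrained:
        if store.has_ckpt("pretrained"):
            sources["pretrained"] = store.load_ckpt("pretrained")[0]
            store.log("pretrain.skip")
        else:
            sources["pretrained"] = pretrain_source_task(
                config.backbone, seed=(config.seed * 131 + 53) % (2**31 - 1)
            )
            store.save_ckpt("pretrained", sources["pretrained"], {"task": "source"})
            store.log("pretrain.done")
    if last < STAGES.index("train"):
        return store

    # -- train (+ shrink search inside _train_one) --------------------------
    trained: dict[str, WeightCollection] = {}
    order = [m for m in MODEL_RECIPES if m in config.models]  # dependency order
    for model_id in order:
        _, _, source_id = MODEL_RECIPES[model_id]
        if MODEL_RECIPES[model_id][0] == "shrink" and last < STAGES.index("shrink"):
            continue
        if source_id and source_id != "pretrained":
            if source_id not in trained:
                store.log("train.blocked", model=model_id, missing=source_id)
                continue
            sources[source_id] = trained[source_id]
        w = _train_one(config, store, model_id, data, sources)
        if w is not None:
            trained[model_id] = w
    if last < STAGES.index("ensemble"):
        return store

    # -- ensembles ----------------------------------------------------------
    template = make_backbone(config.backbone)
    scoreables: dict[str, object] = {}  # id -> callable(x) -> scores, and stage
    stages: dict[str, str] = {}
    for model_id, w in trained.items():
        stages[model_id] = MODEL_RECIPES[model_id][1]

    def _weights_scorer(w: WeightCollection):
        def score(x):
            template.set_weights(w)
            return template.predict_scores(x)
        return score

    for model_id, w in trained.items():
        scoreables[model_id] = _weights_scorer(w)

    ens_meta: dict[str, dict] = {}
    for ens_id, method, constituents in config.ensembles:
        missing = [c for c in constituents if c not in trained]
        if missing:
            store.log("ensemble.blocked", ensemble=ens_id, missing=missing)
            continue
        seed = (config.seed * 131 + 997 + hash(ens_id) % 1000) % (2**31 - 1)
        cons_stage = MODEL_RECIPES[constituents[0]][1]
        if method == "ewa":
            if store.has_ckpt(ens_id):
                merged = store.load_ckpt(ens_id)[0]
            else:
                merged = ewa_ensemble([trained[c] for c in constituents])
                store.save_ckpt(ens_id, merged, {"method": "ewa", "constituents": constituents})
            scoreables[ens_id] = _weights_scorer(merged)
        elif method == "fslsqp":
            if store.has_ckpt(ens_id):
                merged, meta = store.load_ckpt(ens_id)
            else:
                fit, merged = f_slsqp_ensemble(
                    [trained[c] for c in constituents],
                    make_backbone(config.backbone),
                    data,
                    n_restarts=config.slsqp_restarts,
                    seed=seed,
                    stage=cons_stage,
                )
                meta = {
                    "method": "fslsqp", "constituents": constituents,
                    "coefficients": list(fit.coefficients), "error": fit.error,
                }
                store.save_ckpt(ens_id, merged, meta)
            ens_meta[ens_id] = {k: v for k, v in meta.items() if k != "layers"}
            scoreables[ens_id] = _weights_scorer(merged)
        elif method == "agelfs":
            cons_models = []
            for c in constituents:
                m = make_backbone(config.backbone)
                m.set_weights(trained[c])
                cons_models.append(m)
            spec = AGELFSSpec(max_epochs=config.agelfs_epochs, lr=config.lr,
                              batch_size=config.batch_size, seed=seed)
            ens = build_agelfs(spec, cons_models)
            ens, fuzziness, _ = train_agelfs(ens, data, stage=cons_stage)
            ens_meta[ens_id] = dict(ens.sidecar(), constituents=list(constituents))
            scoreables[ens_id] = ens.predict_scores
        else:
            raise ValueError(f"unknown ensemble method {method!r}")
        stages[ens_id] = cons_stage
        store.log("ensemble.done", ensemble=ens_id, method=method)
    if last < STAGES.index("evaluate"):
        return store

    # -- evaluate -----------------------------------------------------------
    store.metrics = []
    thresholds: dict[str, float] = {}
    preds_dir = store.outdir / "predictions"
    for mid, scorer in scoreables.items():
        _, val_key = data.stage_train_val(stages[mid])
        x_va, y_va = data.split(val_key)
        val_preds = PredictionSet(scores=scorer(x_va), labels=y_va)
        t = select_threshold_max_f(val_preds)
        thresholds[mid] = t
        frames = [val_preds.to_frame(split=val_key)]
        for test in config.tests:
            key = _test_split_key(test)
            x_te, y_te = data.split(key)
            preds = PredictionSet(scores=scorer(x_te), labels=y_te)
            frames.append(preds.to_frame(split=key))
            rep = evaluate_predictions(preds, t)
            method = "wald-proportion" if rep.mcc >= 0 else "clopper-pearson"
            ci = mcc_ci(rep.mcc, rep.n, method=method)
            store.metrics.append(
                {
                    "model": mid, "test": test, "threshold": t,
                    "auprc": rep.auprc, "balanced_accuracy": rep.balanced_accuracy,
                    "precision": rep.precision, "recall": rep.recall,
                    "f_score": rep.f_score, "mcc": rep.mcc,
                    "ci_lower": ci.lower, "ci_upper": ci.upper, "n": rep.n,
                    "is_ensemble": mid not in MODEL_RECIPES,
                }
            )
        wio.save_predictions(preds_dir / f"{mid}.csv", frames)
    store.log("evaluate.done", n_models=len(scoreables))
    if last < STAGES.index("compare"):
        store.save()
        return store

    # -- compare ------------------------------------------------------------
    store.comparisons = []
    mrows = pd.DataFrame(store.metrics)
    for test in config.tests:
        sub = mrows[mrows["test"] == test].set_index("model")
        individual = sub[~sub["is_ensemble"]]
        baseline = individual["mcc"].idxmax() if len(individual) else None
        ids = list(sub.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                ra, rb = sub.loc[a], sub.loc[b]
                ma = MetricWithCI(ra["mcc"], _row_ci(ra), int(ra["n"]))
                mb = MetricWithCI(rb["mcc"], _row_ci(rb), int(rb["n"]))
                res = ci_z_test(ma, mb)
                store.comparisons.append(
                    {
                        "test": test, "model_a": a, "model_b": b,
                        "mcc_a": ra["mcc"], "mcc_b": rb["mcc"],
                        "ci_a_lower": ra["ci_lower"], "ci_a_upper": ra["ci_upper"],
                        "ci_b_lower": rb["ci_lower"], "ci_b_upper": rb["ci_upper"],
                        "z": res.z, "p": res.p, "p_rendered": format_p(res.p),
                        "significant": res.significant,
                        "involves_baseline": baseline in (a, b),
                    }
                )
    # EMD diagnostic over every trained checkpoint
    if trained:
        emd = emd_matrix(trained)
        emd.round(6).to_csv(store.outdir / "emd_matrix.csv")
    baselines = {}
    for test in config.tests:
        cand = [
            (m["mcc"], m["model"])
            for m in store.metrics
            if m["test"] == test and not m["is_ensemble"]
        ]
        if cand:
            baselines[test] = max(cand)[1]
    store.meta = {
        "seed": config.seed,
        "thresholds": thresholds,
        "baselines": baselines,
        "ensembles": ens_meta,
        "models_trained": sorted(trained),
    }
    store.save()
    store.log("compare.done", n_comparisons=len(store.comparisons))
    if last < STAGES.index("report"):
        return store

    render_tables(store)
    store.log("report.done")
    return store


def _row_ci(row):
    from .stats_compare import ConfidenceInterval

    return ConfidenceInterval(lower=float(row["ci_lower"]), upper=float(row["ci_upper"]))


def render_tables(store: ResultStore) -> dict[str, pd.DataFrame]:
    """Render metrics.csv and comparisons.csv from a populated store.

    Values are rounded to 4 decimals (full precision stays in
    report.json); p-values below 1e-5 render as "<0.00001"; best-in-
    column and significant-vs-baseline markers are machine-readable
    boolean columns.  Regeneration from an untouched store is
    byte-identical (deterministic ordering and formatting).
    """
    if not store.metrics:
        raise ValueError("empty result store: nothing to render")
    metrics = pd.DataFrame(store.metrics).sort_values(["test", "model"]).reset_index(drop=True)
    metrics["mcc_ci"] = [
        f"{m:.4f} ({lo:.4f}, {hi:.4f})"
        for m, lo, hi in zip(metrics["mcc"], metrics["ci_lower"], metrics["ci_upper"])
    ]
    for col in ("auprc", "balanced_accuracy", "precision", "recall", "f_score", "mcc"):
        metrics[f"best_{col}"] = False
        for test, grp in metrics.groupby("test"):
            metrics.loc[grp[col].idxmax(), f"best_{col}"] = True
    out = metrics.round(4)
    out.to_csv(store.outdir / "metrics.csv", index=False)

    comps = pd.DataFrame(store.comparisons)
    if len(comps):
        comps = comps.sort_values(["test", "model_a", "model_b"]).reset_index(drop=True)
        comps.round(6).to_csv(store.outdir / "comparisons.csv", index=False)
    return {"metrics": out, "comparisons": comps}
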