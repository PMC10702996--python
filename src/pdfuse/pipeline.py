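"""End-to-end orchestration: generate -> preprocess -> (pretrain) -> train ->
(tune) -> evaluate, with YAML config, JSON reports and reproducibility
plumbing.

The deterministic report (``report.json``) contains everything needed to
reproduce a run — config echo, stage seeds, metrics, best hyperparameters —
and deliberately excludes wall-clock timings, which go to a separate
``timings.json`` so that a re-run with the same seed reproduces
``report.json`` byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import evalmetrics, idmo, mobilenetv3, pcfan, phantoms
from .fusion import FusionConfig, preprocess_image
from .idmo import IDMOConfig
from .mobilenetv3 import Hyperparams, ModelConfig
from .pcfan import PCFANConfig
from .phantoms import PhantomSpec

logger = logging.getLogger("pdfuse")

__all__ = [
    "SearchDimension",
    "SearchSpace",
    "DEFAULT_SEARCH_SPACE",
    "PipelineConfig",
    "load_config",
    "save_config",
    "run_pipeline",
    "tune_hyperparameters",
    "REPORT_SCHEMA",
    "validate_report",
]


# ---------------------------------------------------------------------------
# Hyperparameter search space

_BATCH_CHOICES = (8, 16, 32)


@dataclass(frozen=True)
class SearchDimension:
    name: str
    transform: str   # "log10" | "linear" | "choice"
    low: float
    high: float

    def decode(self, theta: float):
        theta = float(np.clip(theta, self.low, self.high))
        if self.transform == "log10":
            return 10.0**theta
        if self.transform == "choice":
            return _BATCH_CHOICES[int(round(theta))]
        return theta

    def encode(self, value) -> float:
        if self.transform == "log10":
            return float(np.log10(value))
        if self.transform == "choice":
            return float(_BATCH_CHOICES.index(value))
        return float(value)


@dataclass
class SearchSpace:
    dimensions: tuple[SearchDimension, ...]

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([d.low for d in self.dimensions])
        hi = np.array([d.high for d in self.dimensions])
        return lo, hi

    def decode(self, theta: np.ndarray) -> dict:
        return {d.name: d.decode(t) for d, t in zip(self.dimensions, theta)}

    def encode(self, values: dict) -> np.ndarray:
        return np.array([d.encode(values[d.name]) for d in self.dimensions])


DEFAULT_SEARCH_SPACE = SearchSpace(dimensions=(
    SearchDimension("learning_rate", "log10", -4.0, -1.0),
    SearchDimension("batch_size", "choice", 0.0, 2.0),
    SearchDimension("weight_decay", "log10", -6.0, -2.0),
    SearchDimension("dropout", "linear", 0.0, 0.5),
    SearchDimension("width_multiplier", "linear", 0.25, 1.0),
))


# ---------------------------------------------------------------------------
# Pipeline configuration

@dataclass
class PipelineConfig:
    out_dir: str = "pdfuse_out"
    n_per_class: int = 100
    image_size: int = 128
    split_fraction: float = 0.8
    seed: int = 0
    deterministic: bool = True
    enable_preprocessing: bool = True
    enable_pcfan: bool = False
    enable_tuning: bool = False
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    pcfan: PCFANConfig = field(default_factory=PCFANConfig)
    pcfan_epochs: int = 10
    model: ModelConfig = field(default_factory=ModelConfig)
    training: Hyperparams = field(default_factory=lambda: Hyperparams(epochs=30))
    idmo: IDMOConfig = field(default_factory=lambda: IDMOConfig(n=6, max_iter=8))
    tuning_proxy_epochs: int = 5


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)


_NESTED = {
    "phantom": PhantomSpec,
    "fusion": FusionConfig,
    "pcfan": PCFANConfig,
    "model": ModelConfig,
    "training": Hyperparams,
    "idmo": IDMOConfig,
}


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED:
            cls = _NESTED[key]
            if cls is ModelConfig and "bneck_specs" in value:
                value["bneck_specs"] = tuple(
                    mobilenetv3.BneckSpec(**s) for s in value["bneck_specs"])
            for tkey in ("stage_channels", "k_search_range", "phi_range"):
                if tkey in value and isinstance(value[tkey], list):
                    value[tkey] = tuple(value[tkey])
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def _stage_seed(seed: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode("utf-8")) % (2**31 - 1)
    h = np.random.SeedSequence([seed, tag])
    return int(h.generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# Stages

def _load_split(manifest: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([phantoms.load_image(p) for p in manifest.path])
    labels = manifest.label.to_numpy(dtype=np.int64)
    return imgs, labels


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Execute all enabled stages in order; returns the deterministic report.

    Writes ``report.json`` (deterministic), ``timings.json``,
    ``history.csv`` (training history) and ``preprocess_stats.csv`` under
    ``config.out_dir``.
    """
    config = config or PipelineConfig()
    os.makedirs(config.out_dir, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {
        "config": _to_plain(config),
        "seeds": {},
        "stages": [],
        "results": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            timings[name] = time.perf_counter() - t0
            report["stages"].append(name)
            logger.info("stage %s done in %.2fs", name, timings[name])
            return out
        return wrap

    # -- generate ----------------------------------------------------------
    gen_seed = _stage_seed(config.seed, "generate")
    report["seeds"]["generate"] = gen_seed

    def _generate():
        spec = replace(config.phantom, image_size=config.image_size)
        return phantoms.generate_dataset(
            config.n_per_class, os.path.join(config.out_dir, "data"),
            spec_defaults=spec, split_fraction=config.split_fraction,
            seed=gen_seed)

    train_m, test_m = stage("generate")(_generate)
    X_train, y_train = _load_split(train_m)
    X_test, y_test = _load_split(test_m)

    # -- preprocess --------------------------------------------------------
    if config.enable_preprocessing:
        def _preprocess():
            stats_rows = []

            def run(split, X, manifest):
                fused = np.empty_like(X)
                for i in range(len(X)):
                    fused[i], st = preprocess_image(X[i], config.fusion)
                    stats_rows.append({"path": manifest.path.iloc[i], **st})
                return fused

            Xtr = run("train", X_train, train_m)
            Xte = run("test", X_test, test_m)
            pd.DataFrame(stats_rows).to_csv(
                os.path.join(config.out_dir, "preprocess_stats.csv"), index=False)
            return Xtr, Xte

        X_train, X_test = stage("preprocess")(_preprocess)

    # -- PCFAN pretraining + refinement --------------------------------------
    if config.enable_pcfan:
        pcfan_seed = _stage_seed(config.seed, "pcfan")
        report["seeds"]["pcfan"] = pcfan_seed

        def _pcfan():
            cfg = replace(config.pcfan, seed=pcfan_seed)
            model, history = pcfan.pretrain_pcfan(
                X_train, cfg, epochs=config.pcfan_epochs, seed=pcfan_seed)
            history.to_csv(os.path.join(config.out_dir, "pcfan_history.csv"),
                           index=False)
            refined_tr = np.stack([
                model.forward(x[None, None])[0, 0] for x in X_train])
            refined_te = np.stack([
                model.forward(x[None, None])[0, 0] for x in X_test])
            report["results"]["pcfan_final_mse"] = float(history.loss.iloc[-1])
            return refined_tr, refined_te

        X_train, X_test = stage("pcfan")(_pcfan)

    # -- tune ----------------------------------------------------------------
    hyper = config.training
    model_cfg = config.model
    if config.enable_tuning:
        best, trace = tune_hyperparameters(
            config, X_train=X_train, y_train=y_train)
        trace.to_csv(os.path.join(config.out_dir, "tuning_trace.csv"), index=False)
        report["results"]["best_hyperparameters"] = _to_plain(best)
        hyper = replace(hyper,
                        learning_rate=best["learning_rate"],
                        batch_size=best["batch_size"],
                        weight_decay=best["weight_decay"])
        model_cfg = replace(model_cfg, dropout=best["dropout"],
                            width_multiplier=best["width_multiplier"])

    # -- train ---------------------------------------------------------------
    train_seed = _stage_seed(config.seed, "train")
    report["seeds"]["train"] = train_seed

    def _train():
        model = mobilenetv3.build_model(replace(model_cfg, seed=train_seed))
        model, history = mobilenetv3.train_classifier(
            model, X_train, y_train, hyper, seed=train_seed,
            X_val=X_test, y_val=y_test)
        history.to_csv(os.path.join(config.out_dir, "history.csv"), index=False)
        model.save(os.path.join(config.out_dir, "classifier.npz"))
        report["results"]["final_train_accuracy"] = float(history.train_acc.iloc[-1])
        return model

    model = stage("train")(_train)

    # -- evaluate ------------------------------------------------------------
    def _evaluate():
        probs, labels = mobilenetv3.predict(model, X_test)
        rep = evalmetrics.classification_report(
            y_test, labels, model_cfg.n_classes, score_matrix=probs)
        return rep

    eval_report = stage("evaluate")(_evaluate)
    report["results"]["evaluation"] = _to_plain(eval_report)
    report["results"]["macro_accuracy"] = eval_report["macro"]["accuracy"]
    report["results"]["macro_f_measure"] = eval_report["macro"]["f_measure"]
    report["results"]["macro_auc"] = eval_report.get("macro_auc")

    validate_report(report)
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(os.path.join(config.out_dir, "timings.json"), "w") as fh:
        json.dump(timings, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# Hyperparameter tuning

def tune_hyperparameters(
    config: PipelineConfig,
    objective=None,
    search_space: SearchSpace = DEFAULT_SEARCH_SPACE,
    X_train: np.ndarray | None = None,
    y_train: np.ndarray | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Minimize validation error over the search space with IDMO.

    By default the objective is the validation error of a short proxy
    training run (``tuning_proxy_epochs`` epochs, fixed seed per evaluation);
    a custom ``objective(theta) -> float`` on the encoded space may be
    injected (used for stubbed recovery tests).
    Returns (decoded best hyperparameters, evaluation trace).
    """
    idmo_cfg = config.idmo
    if idmo_cfg.n * idmo_cfg.max_iter < idmo_cfg.n:
        raise ValueError("tuning budget must cover at least the population size")
    lo, hi = search_space.bounds
    evaluations: list[dict] = []

    if objective is None:
        if X_train is None or y_train is None:
            raise ValueError("tuning without a custom objective needs training data")
        # Hold out a validation fifth of the training set.
        rng = np.random.default_rng(_stage_seed(config.seed, "tune-split"))
        order = rng.permutation(len(X_train))
        n_val = max(1, len(X_train) // 5)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        proxy_seed = _stage_seed(config.seed, "tune-proxy")

        def objective(theta):
            params = search_space.decode(theta)
            m_cfg = replace(config.model, dropout=params["dropout"],
                            width_multiplier=params["width_multiplier"],
                            seed=proxy_seed)
            hyper = replace(config.training,
                            learning_rate=params["learning_rate"],
                            batch_size=params["batch_size"],
                            weight_decay=params["weight_decay"],
                            epochs=config.tuning_proxy_epochs)
            model = mobilenetv3.build_model(m_cfg)
            try:
                model, _ = mobilenetv3.train_classifier(
                    model, X_train[tr_idx], y_train[tr_idx], hyper,
                    seed=proxy_seed)
            except ValueError:
                return 1.0
            _, labels = mobilenetv3.predict(model, X_train[val_idx])
            return float(np.mean(labels != y_train[val_idx]))

    def logged(theta):
        val = float(objective(theta))
        evaluations.append(
            {**{f"theta_{d.name}": t for d, t in zip(search_space.dimensions, theta)},
             "objective": val})
        return val

    best_theta, best_f, _trace = idmo.optimize(logged, (lo, hi), idmo_cfg)
    best = search_space.decode(best_theta)
    best["objective"] = best_f
    return best, pd.DataFrame(evaluations)


# ---------------------------------------------------------------------------
# Report schema

REPORT_SCHEMA = {
    "type": "object",
    "required": ["config", "seeds", "stages", "results"],
    "properties": {
        "config": {"type": "object"},
        "seeds": {"type": "object"},
        "stages": {"type": "array"},
        "results": {
            "type": "object",
            "required": ["evaluation", "macro_accuracy"],
        },
    },
}


def validate_report(report: dict) -> None:
    """Minimal structural validation against REPORT_SCHEMA."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    for key in REPORT_SCHEMA["properties"]["results"]["required"]:
        if key not in report["results"]:
            raise ValueError(f"report.results missing required key {key!r}")
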