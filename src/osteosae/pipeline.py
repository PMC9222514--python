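"""End-to-end orchestration: preprocess -> features -> (tune) -> train -> report.

A :class:`PipelineConfig` fully determines a run; every run writes its
resolved config next to its outputs so any artifact can be regenerated from
the run directory alone.  A single global seed fans out to per-stage seeds
through ``numpy.random.SeedSequence([seed, stage_index])`` with fixed stage
indices (data=0, network=1, training=2, tuning=3, split=4), so stages can be
re-run in isolation and still match a full run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import dssae, metrics, synthetic, wdo
from .filtering import (
    BilateralParams,
    ImagePatch,
    InputError,
    ParameterError,
    bilateral_filter,
    enhance_contrast,
    gaussian_filter,
    load_patches,
)
from .squeezenet import FeatureMatrix, build_network, default_spec, extract_features

__all__ = ["PipelineConfig", "run", "evaluate", "stage_seed"]

logger = logging.getLogger(__name__)

_STAGES = {"data": 0, "network": 1, "training": 2, "tuning": 3, "split": 4}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), _STAGES[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _check_fields(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ParameterError(f"unknown field(s) in {section}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Serializable description of one classification run."""

    data: dict = field(default_factory=lambda: {"kind": "synthetic_images"})
    filtering: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    tuning: dict = field(default_factory=dict)
    split: str = "80/20"
    seed: int = 0

    _DATA_KEYS = {"kind", "n_per_class", "patch_size", "separability", "noise_sd",
                  "dim", "separation", "covariance", "directory", "manifest", "csv"}
    _FILT_KEYS = {"method", "sigma_s", "sigma_r", "radius", "enhance"}
    _NET_KEYS = {"input_size", "tap_point", "num_classes", "weights"}
    _CLF_KEYS = {"hidden_dims", "epochs", "batch_size", "learning_rate", "rho",
                 "c_s", "c_w", "fine_tune_epochs"}
    _TUNE_KEYS = {"enabled", "population_size", "iterations", "alpha", "g", "RT",
                  "c", "max_velocity", "boundary", "space"}

    def __post_init__(self) -> None:
        _check_fields("data", self.data, self._DATA_KEYS)
        _check_fields("filtering", self.filtering, self._FILT_KEYS)
        _check_fields("network", self.network, self._NET_KEYS)
        _check_fields("classifier", self.classifier, self._CLF_KEYS)
        _check_fields("tuning", self.tuning, self._TUNE_KEYS)
        if self.split not in ("80/20", "70/30"):
            raise ParameterError("split preset must be '80/20' or '70/30'")

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        allowed = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        _check_fields("config", doc, allowed)
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return {
            "data": self.data, "filtering": self.filtering, "network": self.network,
            "classifier": self.classifier, "tuning": self.tuning,
            "split": self.split, "seed": self.seed,
        }


def _preprocess(patches: Sequence[ImagePatch], cfg: dict) -> list[ImagePatch]:
    method = cfg.get("method", "bilateral")
    enhance = cfg.get("enhance", "clahe")
    out = []
    for p in patches:
        q = p.normalized()
        if method == "bilateral":
            q = bilateral_filter(q, params=BilateralParams(
                sigma_s=cfg.get("sigma_s", 2.0), sigma_r=cfg.get("sigma_r", 0.1),
                radius=cfg.get("radius")))
        elif method == "gaussian":
            q = gaussian_filter(q, cfg.get("sigma_s", 2.0), cfg.get("radius"))
        elif method != "none":
            raise ParameterError(f"unknown filtering method {method!r}")
        if enhance != "none":
            if q.is_color:
                q = ImagePatch(q.pixels.mean(axis=2), label=q.label, source=q.source)
            q = enhance_contrast(q, enhance)
        out.append(q)
    return out


def _load_data(cfg: dict, seed: int):
    """Returns (patches or None, features or None, labels or None)."""
    kind = cfg.get("kind", "synthetic_images")
    if kind == "synthetic_images":
        spec = synthetic.ImageGenSpec(
            n_per_class=tuple(cfg.get("n_per_class", (345, 263, 536))),
            patch_size=cfg.get("patch_size", 128),
            separability=cfg.get("separability", 1.0),
            noise_sd=cfg.get("noise_sd", 0.02),
            seed=seed,
        )
        return synthetic.generate_images(spec), None, None
    if kind == "synthetic_features":
        spec = synthetic.FeatureGenSpec(
            n_per_class=tuple(cfg.get("n_per_class", (150, 150, 150))),
            dim=cfg.get("dim", 10),
            separation=cfg.get("separation", 6.0),
            covariance=cfg.get("covariance", "isotropic"),
            seed=seed,
        )
        X, y = synthetic.generate_features(spec)
        return None, X, y
    if kind == "image_dir":
        return load_patches(cfg["directory"], cfg.get("manifest")), None, None
    if kind == "feature_csv":
        import pandas as pd

        df = pd.read_csv(cfg["csv"])
        if "label" not in df.columns:
            raise InputError("feature CSV needs a 'label' column")
        y = [str(v) for v in df["label"]]
        X = df.drop(columns=[c for c in ("label", "sample_id") if c in df.columns]).to_numpy(float)
        return None, X, y
    raise ParameterError(f"unknown data kind {kind!r}")


def run(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write the run directory; returns the summary dict.

    Artifacts: resolved_config.yaml, model file, per-split metric reports
    (CSV + Markdown + confusion CSV), tuning history CSV when tuning is on,
    and summary.json.  On a stage failure a FAILED marker records the stage
    and the exception before it is re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    stage = "data"
    try:
        t0 = time.time()
        patches, X, y = _load_data(config.data, stage_seed(config.seed, "data"))
        if patches is not None:
            stage = "preprocess"
            logger.info("preprocessing %d patches", len(patches))
            patches = _preprocess(patches, config.filtering)
            stage = "features"
            net = build_network(
                default_spec(input_size=config.network.get("input_size", 128),
                             num_classes=config.network.get("num_classes", 3)),
                seed=stage_seed(config.seed, "network"),
            )
            if config.network.get("weights"):
                from .squeezenet import load_pretrained

                net = load_pretrained(config.network["weights"], net.spec)
            fm = extract_features(patches, net, config.network.get("tap_point"))
            X = fm.values
            y = [p.label for p in patches]
            fm.to_csv(out / "features.csv")

        stage = "split"
        frac = 0.8 if config.split == "80/20" else 0.7
        tr, te = synthetic.stratified_split(y, frac, seed=stage_seed(config.seed, "split"))
        class_names = tuple(sorted(set(y), key=lambda c: (c not in synthetic.CLASS_NAMES,
                                                          synthetic.CLASS_NAMES.index(c)
                                                          if c in synthetic.CLASS_NAMES else c)))

        stage = "train"
        clf = dict(config.classifier)
        hidden_dims = tuple(clf.pop("hidden_dims", (256, 128, 64, 32)))
        train_cfg = dssae.TrainConfig(seed=stage_seed(config.seed, "training"), **clf)
        X_tr, y_tr = X[tr], [y[i] for i in tr]
        tuned = None
        if config.tuning.get("enabled", False):
            stage = "tune"
            tune_cfg = {k: v for k, v in config.tuning.items() if k not in ("enabled", "space")}
            wcfg = wdo.WDOConfig(seed=stage_seed(config.seed, "tuning"), **tune_cfg)
            space = _space_from_config(config.tuning.get("space"))
            best, model, result = wdo.tune_dssae(
                X_tr, y_tr, space=space, config=wcfg,
                hidden_dims=hidden_dims, base_train=train_cfg,
            )
            result.history.to_csv(out / "wdo_history.csv", index=False)
            tuned = {k: (float(v) if isinstance(v, float) else v) for k, v in best.items()}
        else:
            model = dssae.train_dssae(X_tr, y_tr, hidden_dims, train_cfg, class_names=class_names)
        dssae.save_model(model, out / "model.npz")

        stage = "evaluate"
        reports = {}
        for name, idx in (("train", tr), ("test", te)):
            preds, _ = dssae.predict(model, X[idx])
            cm = metrics.confusion_from_predictions([y[i] for i in idx], preds, model.class_names)
            table = metrics.render_report(cm, out, name=f"metrics_{name}")
            reports[name] = {
                "error_rate": wdo.fitness(preds, [y[i] for i in idx]),
                "accuracy": 100.0 - wdo.fitness(preds, [y[i] for i in idx]),
                "macro": {k: round(float(v), 6) for k, v in table.loc["Average"].items()},
            }

        summary = {
            "seed": config.seed,
            "split": config.split,
            "n_train": int(len(tr)),
            "n_test": int(len(te)),
            "class_names": list(model.class_names),
            "tuned_hyperparameters": tuned,
            "results": reports,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        logger.info("run finished in %.1fs", time.time() - t0)
        return summary
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise


def _space_from_config(space_cfg) -> wdo.SearchSpace | None:
    if not space_cfg:
        return None
    dims = []
    for d in space_cfg:
        d = dict(d)
        kind = d.pop("kind")
        if kind == "grid":
            dims.append(wdo.Dimension(d["name"], "grid", grid=tuple(d["values"])))
        else:
            dims.append(wdo.Dimension(d["name"], kind, lower=d["lower"], upper=d["upper"]))
    return wdo.SearchSpace(dims)


def evaluate(run_dir: str | Path, patches: Sequence[ImagePatch] | None = None,
             features: np.ndarray | None = None, labels: Sequence[str] | None = None,
             out_dir: str | Path | None = None) -> dict:
    """Apply a finished run's preprocessing + network + model to new data.

    Data enters either as image patches (the persisted filtering and network
    settings are replayed) or as a ready feature matrix with labels.
    Returns {"error_rate", "accuracy", "table"}.
    """
    run_path = Path(run_dir)
    config = PipelineConfig.from_yaml(run_path / "resolved_config.yaml")
    model = dssae.load_model(run_path / "model.npz")
    if patches is not None:
        if len(patches) == 0:
            raise InputError("no patches to evaluate")
        pre = _preprocess(patches, config.filtering)
        net = build_network(
            default_spec(input_size=config.network.get("input_size", 128),
                         num_classes=config.network.get("num_classes", 3)),
            seed=stage_seed(config.seed, "network"),
        )
        fm = extract_features(pre, net, config.network.get("tap_point"))
        features = fm.values
        labels = [p.label for p in pre]
    if features is None or labels is None:
        raise InputError("provide patches or (features, labels)")
    preds, _ = dssae.predict(model, features)
    cm = metrics.confusion_from_predictions(list(labels), preds, model.class_names)
    table = metrics.render_report(cm, out_dir, name="metrics_eval") if out_dir else metrics.class_metrics_table(cm)
    err = wdo.fitness(preds, list(labels))
    return {"error_rate": err, "accuracy": 100.0 - err, "table": table}
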