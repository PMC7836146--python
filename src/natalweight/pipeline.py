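"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate.

Each stage is a pure function over in-memory objects; the CLI maps them onto
files.  A single global seed deterministically derives per-stage seeds (via
a stable hash split) so identical configs yield byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, network, preprocess
from .baselines import BaselineConfig, fit_reference_model
from .preprocess import (FEATURE_NAMES, LABEL_NAME, NormalizationSpec,
                         build_feature_table, eligibility_filter,
                         fit_normalizer, normalize, denormalize_scalar,
                         normalize_scalar)
from .records import Cohort, STATIC_PREDICTORS
from .simulate import GeneratorConfig, generate_cohort

__all__ = [
    "stage_seed",
    "FeatureSet",
    "prepare_features",
    "train_hybrid",
    "predict_hybrid",
    "compare_models",
    "RunConfig",
    "run_pipeline",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (below 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class FeatureSet:
    """Normalized features with split assignment and metadata.

    ``X`` holds the 16 normalized predictors (training extrema in ``spec``),
    ``y`` the raw birthweights in grams, ``X_raw`` the unnormalized features
    (the uterine-height column is needed by the empirical formula baseline).
    """

    X: np.ndarray
    X_raw: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame
    train_mask: np.ndarray
    spec: NormalizationSpec
    exclusions: list = field(default_factory=list)

    @property
    def label_entry(self) -> tuple[float, float]:
        return self.spec.entry(LABEL_NAME)

    def y_normalized(self) -> np.ndarray:
        return np.array([normalize_scalar(v, self.label_entry) for v in self.y])

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        df.insert(0, "id", self.meta["id"].values)
        df["parity"] = self.meta["parity"].values
        df["delivery_week"] = self.meta["delivery_week"].values
        df[LABEL_NAME] = self.y
        df["split"] = np.where(self.train_mask, "train", "test")
        return df


def prepare_features(cohort: Cohort, scheduled_visits: int = 8,
                     train_fraction: float = 0.8, seed: int = 0) -> FeatureSet:
    """Filter, impute, split and normalize a cohort into model-ready features.

    The min-max spec (including the label entry) is learned on the training
    rows only; test rows are transformed with it and clamped to [-1, 1].
    """
    eligible, exclusions = eligibility_filter(cohort, scheduled_visits=scheduled_visits)
    if len(eligible) < 2:
        raise ValueError("fewer than 2 eligible records after filtering")
    X_raw, y, meta = build_feature_table(eligible)
    idx_train, idx_test = evaluation._split_indices(len(y), train_fraction, seed)
    train_mask = np.zeros(len(y), dtype=bool)
    train_mask[idx_train] = True

    labelled = train_mask & np.isfinite(y)
    table = np.column_stack([X_raw[labelled], y[labelled]])
    spec = fit_normalizer(table, names=tuple(FEATURE_NAMES) + (LABEL_NAME,))
    feat_spec = NormalizationSpec(names=tuple(FEATURE_NAMES),
                                  x_min=spec.x_min[:-1], x_max=spec.x_max[:-1])
    X = normalize(X_raw, feat_spec)
    return FeatureSet(X=X, X_raw=X_raw, y=y, meta=meta, train_mask=train_mask,
                      spec=spec, exclusions=exclusions)


def train_hybrid(fs: FeatureSet, cfg: network.TrainConfig):
    """Train the hybrid network on the FeatureSet's training rows."""
    mask = fs.train_mask & np.isfinite(fs.y)
    return network.train(fs.X[mask], fs.y_normalized()[mask], cfg)


def predict_hybrid(fs: FeatureSet, params: network.HybridNetParams,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Hybrid predictions in grams over the selected rows (default: all)."""
    if mask is None:
        mask = np.ones(len(fs.y), dtype=bool)
    return network.predict(fs.X[mask], params, fs.label_entry)


_UH_COL = STATIC_PREDICTORS.index("uh")


def compare_models(fs: FeatureSet, train_cfg: network.TrainConfig,
                   kinds=("zhuo", "linear", "svr", "rf", "bpnn", "cnn"),
                   include_hybrid: bool = True, seed: int = 0) -> pd.DataFrame:
    """Fit every requested baseline plus the hybrid model on the shared
    train/test split and report test MRE %, +/-250 g accuracy % and
    SGA/AGA/LGA category accuracy %.
    """
    tr = fs.train_mask & np.isfinite(fs.y)
    te = ~fs.train_mask & np.isfinite(fs.y)
    y_tr, y_te = fs.y[tr], fs.y[te]
    rows = []

    def add(method, pred):
        rows.append({
            "method": method,
            "mre_pct": 100.0 * evaluation.mre(y_te, pred),
            "accuracy_pct": 100.0 * evaluation.accuracy_250(y_te, pred),
            "category_accuracy_pct": 100.0 * evaluation.category_accuracy(y_te, pred),
        })

    for kind in kinds:
        cfg = BaselineConfig(kind=kind, seed=seed)
        if kind == "zhuo":
            model = fit_reference_model(cfg, fs.X_raw[tr][:, _UH_COL], y_tr)
            add("Zhuo formula", model.predict(fs.X_raw[te][:, _UH_COL]))
        else:
            model = fit_reference_model(cfg, fs.X[tr], y_tr)
            add(kind.upper() if kind != "linear" else "Linear-R",
                model.predict(fs.X[te]))
    if include_hybrid:
        params, _ = train_hybrid(fs, train_cfg)
        add("Hybrid-LSTM", predict_hybrid(fs, params, mask=te))
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    generator: GeneratorConfig
    training: network.TrainConfig
    scheduled_visits: int = 8
    train_fraction: float = 0.8
    k_folds: int = 5
    seed: int = 0
    compare_kinds: tuple = ("zhuo", "linear", "rf")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("generator", "training"):
            if key not in d:
                raise ValueError(f"config missing required section: {key}")
        gen = GeneratorConfig.from_dict(d.pop("generator"))
        trd = d.pop("training")
        tr = network.TrainConfig(**{**trd, "fc_hidden": tuple(trd.get("fc_hidden", (20, 12)))})
        if "compare_kinds" in d:
            d["compare_kinds"] = tuple(d["compare_kinds"])
        return cls(generator=gen, training=tr, **d)

    def config_hash(self) -> str:
        import json

        payload = json.dumps({
            "generator": self.generator.to_dict(),
            "training": vars(self.training) | {"fc_hidden": list(self.training.fc_hidden)},
            "scheduled_visits": self.scheduled_visits,
            "train_fraction": self.train_fraction,
            "k_folds": self.k_folds,
            "seed": self.seed,
            "compare_kinds": list(self.compare_kinds),
        }, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: RunConfig):
    """Execute the full in-memory pipeline; returns a dict of artifacts."""
    gen_cfg = config.generator
    gen_cfg.seed = stage_seed(config.seed, "simulate")
    cohort = generate_cohort(gen_cfg)

    fs = prepare_features(cohort, scheduled_visits=config.scheduled_visits,
                          train_fraction=config.train_fraction,
                          seed=stage_seed(config.seed, "split"))

    train_cfg = config.training
    train_cfg.seed = stage_seed(config.seed, "train")
    params, log = train_hybrid(fs, train_cfg)

    test = ~fs.train_mask & np.isfinite(fs.y)
    pred = predict_hybrid(fs, params, mask=test)
    report = evaluation.subgroup_report(
        fs.y[test], pred,
        fs.meta["parity"].values[test],
        fs.meta["delivery_week"].values[test],
    )
    comparison = compare_models(fs, train_cfg, kinds=config.compare_kinds,
                                include_hybrid=False,
                                seed=stage_seed(config.seed, "baselines"))
    comparison = pd.concat([comparison, pd.DataFrame([{
        "method": "Hybrid-LSTM",
        "mre_pct": 100.0 * report.mre,
        "accuracy_pct": 100.0 * report.accuracy_250,
        "category_accuracy_pct": 100.0 * report.category_accuracy,
    }])], ignore_index=True)
    return {
        "cohort": cohort,
        "features": fs,
        "params": params,
        "train_log": log,
        "predictions": pd.DataFrame({
            "id": fs.meta["id"].values[test],
            "y_true": fs.y[test],
            "y_pred": pred,
        }),
        "report": report,
        "comparison": comparison,
        "config_hash": config.config_hash(),
    }
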