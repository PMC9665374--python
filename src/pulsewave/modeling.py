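"""Outlier exclusion and the 13-model ensemble predictor.

Training follows the study's two-step recipe: Isolation Forest outlier
exclusion on the feature table, then 13 constituent classifiers trained
with deliberately varied ingredients — model family (4 random forests,
5 gradient-boosted tree configurations, 4 elastic nets), random feature
subsets, bootstrap resamples of the training subjects, and varied LVEDP
label-threshold pairs.  Tree depths are confined to 3–7.  Each model's
continuous output is min–max normalized against its own training
outputs (clipped to [0, 1] on new data) and the ensemble risk score is
the arithmetic mean of the 13 normalized outputs.

The exact constituent hyperparameter table of the original predictor is
not public; the defaults here are documented reconstructions that keep
the stated family counts and depth limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .errors import (ConfigurationError, EmptyStratumError, SchemaError)

__all__ = [
    "ModelSpec", "EnsembleModel", "default_model_specs",
    "detect_outliers", "train_ensemble", "cross_validate",
    "ensemble_predict", "labels_for_spec",
]

#: (elevated_def, nonelevated_def) mmHg pairs cycled across constituents;
#: the first is the primary-objective definition (>=25 vs <=12).
DEFAULT_THRESHOLD_PAIRS = ((25.0, 12.0), (25.0, 15.0), (20.0, 12.0))


@dataclass
class ModelSpec:
    """Specification of one constituent model."""

    model_id: int                      # 1..13
    family: str                        # random_forest | xgboost | elastic_net
    feature_subset: list               # feature names this model sees
    subject_sampling: str = "bootstrap"   # "bootstrap" | "full"
    label_threshold: tuple = (25.0, 12.0)
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("random_forest", "xgboost", "elastic_net"):
            raise ConfigurationError(f"unknown model family {self.family!r}")
        depth = self.hyperparameters.get("max_depth")
        if self.family in ("random_forest", "xgboost") and depth is not None \
                and not (3 <= depth <= 7):
            raise ConfigurationError("tree max_depth must be within [3, 7]")


def default_model_specs(feature_names, seed: int = 0,
                        subset_range: tuple = (89, 194)) -> list[ModelSpec]:
    """The 13 default constituent specs.

    ``subset_range`` is the nominal per-model feature-subset size range;
    it is clipped to the number of available columns, so narrow feature
    tables simply use proportionally large subsets.
    """
    names = list(feature_names)
    n = len(names)
    lo = min(max(1, subset_range[0]), n)
    hi = min(max(lo, subset_range[1]), n)
    # narrow tables: still vary the subsets rather than always using all
    if hi == n and lo == n and n > 4:
        lo = max(1, int(0.7 * n))
    rng = np.random.default_rng(seed)

    plans = (
        [("random_forest", {"max_depth": d}) for d in (3, 4, 5, 7)]
        + [("xgboost", {"max_depth": d, "learning_rate": lr})
           for d, lr in ((3, 0.1), (4, 0.05), (5, 0.05), (6, 0.03), (7, 0.03))]
        + [("elastic_net", {"l1_ratio": r}) for r in (0.15, 0.4, 0.6, 0.85)]
    )
    specs = []
    for i, (family, hp) in enumerate(plans):
        size = int(rng.integers(lo, hi + 1))
        subset = sorted(rng.choice(names, size=size, replace=False).tolist())
        specs.append(ModelSpec(
            model_id=i + 1, family=family, feature_subset=subset,
            subject_sampling="bootstrap",
            label_threshold=DEFAULT_THRESHOLD_PAIRS[i % len(DEFAULT_THRESHOLD_PAIRS)],
            hyperparameters=hp))
    return specs


def detect_outliers(features: pd.DataFrame, contamination: float = 0.05,
                    seed: int = 0) -> pd.Series:
    """Isolation-Forest exclusion flags (True = outlier), deterministic."""
    if not (0.0 < contamination < 0.5):
        raise ConfigurationError("contamination must be in (0, 0.5)")
    X = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise SchemaError("feature table contains non-finite values")
    Xs = StandardScaler().fit_transform(X)
    forest = IsolationForest(n_estimators=200, contamination=contamination,
                             random_state=int(seed))
    flags = forest.fit_predict(Xs) == -1
    return pd.Series(flags, index=features.index, name="outlier")


def labels_for_spec(subjects: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    """Binary labels under the spec's (elevated, non-elevated) definitions;
    subjects in neither group are dropped."""
    elev_def, nonelev_def = spec.label_threshold
    lv = subjects["lvedp"]
    y = pd.Series(np.nan, index=subjects.index, dtype=float)
    y[lv >= elev_def] = 1.0
    y[lv <= nonelev_def] = 0.0
    return y.dropna().astype(int)


def _build_estimator(spec: ModelSpec, seed: int):
    hp = spec.hyperparameters
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 300),
            max_depth=hp.get("max_depth", 5),
            max_features="sqrt", random_state=seed, n_jobs=1)
    if spec.family == "xgboost":
        return XGBClassifier(
            n_estimators=hp.get("n_estimators", 200),
            max_depth=hp.get("max_depth", 4),
            learning_rate=hp.get("learning_rate", 0.05),
            subsample=hp.get("subsample", 0.9),
            colsample_bytree=hp.get("colsample_bytree", 0.9),
            reg_lambda=hp.get("reg_lambda", 1.0),
            random_state=seed, n_jobs=1, eval_metric="logloss",
            verbosity=0)
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(
            solver="saga",
            l1_ratio=hp.get("l1_ratio", 0.5), C=hp.get("C", 1.0),
            max_iter=hp.get("max_iter", 5000), random_state=seed))


def _score(estimator, X: np.ndarray) -> np.ndarray:
    return estimator.predict_proba(X)[:, 1]


@dataclass
class FittedConstituent:
    spec: ModelSpec
    estimator: object
    norm_min: float
    norm_max: float

    def normalized_output(self, X: np.ndarray) -> np.ndarray:
        raw = _score(self.estimator, X)
        span = self.norm_max - self.norm_min
        if span <= 0:
            return np.full(raw.shape, 0.5)
        return np.clip((raw - self.norm_min) / span, 0.0, 1.0)


@dataclass
class EnsembleModel:
    """13 fitted constituents plus their output normalizers."""

    constituents: list
    feature_columns: list
    seed: int

    def predict(self, features: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.feature_columns if c not in features.columns]
        if missing:
            raise SchemaError(f"missing feature columns: {missing[:5]}...")
        outs = []
        for fc in self.constituents:
            X = features[fc.spec.feature_subset].to_numpy(dtype=float)
            outs.append(fc.normalized_output(X))
        score = np.mean(outs, axis=0)
        return pd.Series(score, index=features.index, name="risk_score")


def train_ensemble(features: pd.DataFrame, subjects: pd.DataFrame,
                   specs: list[ModelSpec] | None = None,
                   seed: int = 0) -> EnsembleModel:
    """Fit the 13 constituents; deterministic for a fixed seed.

    ``subjects`` must be indexed like ``features`` and carry an
    ``lvedp`` column.  Each constituent trains on the subjects selected
    by its own label thresholds, on a stratified bootstrap resample
    when ``subject_sampling == "bootstrap"``; its min–max output
    normalizer is fit on the model's outputs over its full (pre-
    bootstrap) training selection.
    """
    subjects = subjects.loc[features.index]
    if specs is None:
        specs = default_model_specs(features.columns, seed=seed)
    ss = np.random.SeedSequence(seed).spawn(len(specs))
    constituents = []
    for spec, child in zip(specs, ss):
        rng = np.random.default_rng(child)
        est_seed = int(child.generate_state(1)[0] % (2 ** 31))
        y = labels_for_spec(subjects, spec)
        if (y == 1).sum() == 0 or (y == 0).sum() == 0:
            raise EmptyStratumError(
                f"model {spec.model_id}: a label class is empty under "
                f"thresholds {spec.label_threshold}")
        idx = y.index
        if spec.subject_sampling == "bootstrap":
            # stratified bootstrap keeps both classes present
            parts = []
            for cls in (0, 1):
                members = idx[y == cls]
                parts.append(rng.choice(members, size=members.size, replace=True))
            fit_idx = np.concatenate(parts)
        else:
            fit_idx = idx.to_numpy()
        Xf = features.loc[fit_idx, spec.feature_subset].to_numpy(dtype=float)
        yf = y.loc[fit_idx].to_numpy()
        est = _build_estimator(spec, est_seed)
        est.fit(Xf, yf)
        train_out = _score(est, features.loc[idx, spec.feature_subset]
                           .to_numpy(dtype=float))
        constituents.append(FittedConstituent(
            spec=spec, estimator=est,
            norm_min=float(train_out.min()), norm_max=float(train_out.max())))
    return EnsembleModel(constituents=constituents,
                         feature_columns=list(features.columns), seed=seed)


def ensemble_predict(model: EnsembleModel, features: pd.DataFrame) -> pd.Series:
    """Ensemble risk score in [0, 1] (mean of normalized constituent outputs)."""
    return model.predict(features)


def cross_validate(spec: ModelSpec, features: pd.DataFrame,
                   subjects: pd.DataFrame, folds: int = 5,
                   iterations: int = 100, seed: int = 0) -> np.ndarray:
    """Out-of-fold AUCs from stratified k-fold CV repeated ``iterations``
    times with re-randomized fold assignment; shape (iterations * folds,)."""
    subjects = subjects.loc[features.index]
    y = labels_for_spec(subjects, spec)
    counts = y.value_counts()
    if len(counts) < 2:
        raise EmptyStratumError("both classes must be present")
    if counts.min() < folds:
        raise ConfigurationError(
            f"smallest class has {counts.min()} members < {folds} folds")
    X = features.loc[y.index, spec.feature_subset].to_numpy(dtype=float)
    yv = y.to_numpy()
    ss = np.random.SeedSequence(seed).spawn(iterations)
    aucs = []
    for child in ss:
        it_seed = int(child.generate_state(1)[0] % (2 ** 31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=it_seed)
        for k, (tr, te) in enumerate(skf.split(X, yv)):
            est = _build_estimator(spec, it_seed + k)
            est.fit(X[tr], yv[tr])
            aucs.append(roc_auc_score(yv[te], _score(est, X[te])))
    return np.asarray(aucs)
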