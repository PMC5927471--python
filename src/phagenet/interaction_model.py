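"""Random-forest classification of phage-bacterium interactions.

The four evidence channels of :mod:`phagenet.feature_scoring` feed a
random forest that classifies pairs as interacting or not.  The model is
tuned by repeated stratified k-fold cross-validation (5 folds x 10
repeats by default) maximizing ROC AUC over the features-per-split
hyperparameter, and its generalization performance is estimated by
nested validation: repeated stratified 80/20 splits with inner tuning on
the training portion only.

Missingness handling follows the evidence logic of the scoring stage:

* rows with *no* score on any channel carry no information and are
  excluded from fitting; at prediction time they are classified as
  not interacting (probability 0) without consulting the forest;
* rows with at least one score have their absent channels imputed as 0
  ("no evidence") alongside a per-channel missingness indicator column,
  so the forest can distinguish a true 0 from an absent score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from .feature_scoring import FeatureVector

logger = logging.getLogger("phagenet")

FEATURES = list(FeatureVector.FEATURES)
POSITIVE, NEGATIVE = "interacts", "not_interacting"


# ---------------------------------------------------------------------------
# Feature encoding
# ---------------------------------------------------------------------------

def encode_features(table: pd.DataFrame,
                    features: Sequence[str] | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode a feature table into a model matrix.

    Returns ``(X, usable_mask, column_names)`` where ``usable_mask``
    flags rows with at least one present score.  Missing values are
    imputed as 0 and mirrored by ``<name>_missing`` indicator columns.
    """
    features = list(features or [f for f in FEATURES if f in table.columns])
    if not features:
        raise ValueError("no feature columns found")
    values = table[features].to_numpy(dtype=float)
    missing = np.isnan(values)
    usable = ~missing.all(axis=1)
    X = np.hstack([np.nan_to_num(values, nan=0.0), missing.astype(float)])
    names = features + [f"{f}_missing" for f in features]
    return X, usable, names


def _labels_to_binary(labels: Sequence) -> np.ndarray:
    mapping = {POSITIVE: 1, NEGATIVE: 0, "positive": 1, "negative": 0,
               1: 1, 0: 0, True: 1, False: 0}
    try:
        return np.array([mapping[l] for l in labels], dtype=int)
    except KeyError as err:
        raise ValueError(f"unrecognized label {err.args[0]!r}") from None


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_points(scores: Sequence[float], labels: Sequence,
               ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep plus trapezoid AUC.

    Returns ``(fpr, tpr, auc)``; the curve starts at (0, 0) and ends at
    (1, 1).  Requires both classes to be present.
    """
    y = _labels_to_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC is undefined with a single class")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def _sens_spec(y_true: np.ndarray, prob: np.ndarray,
               threshold: float) -> tuple[float, float]:
    pred = (prob >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Random-forest training configuration.

    ``mtry_grid`` is the candidate grid for the features-per-split
    hyperparameter (``None``: 2, 4 and 6 of the 8 encoded columns);
    tuning maximizes mean inner-CV AUC over ``cv_folds`` x ``cv_repeats``
    stratified folds.  The decision threshold on the interaction
    probability defaults to 0.5.
    """

    n_estimators: int = 50
    cv_folds: int = 5
    cv_repeats: int = 10
    mtry_grid: tuple[int, ...] | None = None
    threshold: float = 0.5
    importance_method: str = "permutation"  # or "retrain"


@dataclass
class TrainedClassifier:
    forest: RandomForestClassifier
    mtry: int
    threshold: float
    feature_names: list[str]
    cv_results: pd.DataFrame  # mtry x repeat AUCs from tuning
    n_used: int
    n_all_missing: int
    config: "ModelConfig | None" = None
    seed: int | None = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict_proba(X)[:, 1]

    def save(self, path) -> None:
        """Serialize the model, its config and seed to one archive."""
        import joblib
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        import joblib
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path!r} does not hold a TrainedClassifier")
        return model


@dataclass
class ModelPerformance:
    """Per-outer-iteration nested-validation performance."""

    auc: list[float]
    sensitivity: list[float]
    specificity: list[float]
    roc_curves: list[tuple[np.ndarray, np.ndarray]]

    @property
    def median_auc(self) -> float:
        return float(np.median(self.auc))

    @property
    def median_sensitivity(self) -> float:
        return float(np.median(self.sensitivity))

    @property
    def median_specificity(self) -> float:
        return float(np.median(self.specificity))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": range(len(self.auc)),
                             "auc": self.auc,
                             "sensitivity": self.sensitivity,
                             "specificity": self.specificity})


def _prepare(table: pd.DataFrame, labels: Sequence | None):
    if labels is None:
        if "label" not in table.columns:
            raise ValueError("no labels given and no 'label' column present")
        labels = table["label"]
    y = _labels_to_binary(list(labels))
    X, usable, names = encode_features(table)
    return X[usable], y[usable], names, int((~usable).sum())


def _tune_mtry(X: np.ndarray, y: np.ndarray, config: ModelConfig,
               rng: np.random.Generator) -> tuple[int, pd.DataFrame]:
    n_cols = X.shape[1]
    grid = config.mtry_grid or tuple(
        m for m in (2, 4, 6) if m <= n_cols) or (n_cols,)
    cv = RepeatedStratifiedKFold(n_splits=config.cv_folds,
                                 n_repeats=config.cv_repeats,
                                 random_state=int(rng.integers(2**31)))
    splits = list(cv.split(X, y))
    rows = []
    for mtry in grid:
        forest = RandomForestClassifier(
            n_estimators=config.n_estimators, max_features=mtry,
            random_state=int(rng.integers(2**31)), n_jobs=1)
        aucs = []
        for tr, te in splits:
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            f = clone(forest).fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], f.predict_proba(X[te])[:, 1]))
        rows.append({"mtry": mtry,
                     "mean_auc": float(np.mean(aucs)) if aucs else np.nan,
                     "n_folds": len(aucs)})
    results = pd.DataFrame(rows)
    if results["mean_auc"].notna().any():
        best = int(results.loc[results["mean_auc"].idxmax(), "mtry"])
    else:  # every fold degenerate: fall back to the smallest candidate
        logger.warning("hyperparameter tuning had no usable CV fold; "
                       "falling back to mtry=%d", grid[0])
        best = int(grid[0])
    return best, results


def train_classifier(table: pd.DataFrame, labels: Sequence | None = None,
                     config: ModelConfig | None = None,
                     seed: int = 0) -> TrainedClassifier:
    """Tune and fit the interaction forest on a labeled feature table.

    All-missing rows are excluded from fitting (they are handled by rule
    at prediction time); the features-per-split parameter is chosen by
    repeated stratified CV maximizing AUC and the forest is then refit on
    every usable row.
    """
    config = config or ModelConfig()
    X, y, names, n_all_missing = _prepare(table, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes after exclusions")
    if np.bincount(y).min() < 2:
        raise ValueError("need >= 2 rows per class")
    rng = np.random.default_rng(seed)
    mtry, cv_results = _tune_mtry(X, y, config, rng)
    forest = RandomForestClassifier(
        n_estimators=config.n_estimators, max_features=mtry,
        random_state=int(rng.integers(2**31)), n_jobs=1).fit(X, y)
    logger.info("trained interaction forest: mtry=%d on %d usable rows "
                "(%d all-missing excluded)", mtry, len(y), n_all_missing)
    return TrainedClassifier(forest=forest, mtry=mtry,
                             threshold=config.threshold,
                             feature_names=names, cv_results=cv_results,
                             n_used=len(y), n_all_missing=n_all_missing,
                             config=config, seed=seed)


def nested_cv(table: pd.DataFrame, labels: Sequence | None = None,
              outer_iters: int = 25, test_fraction: float = 0.2,
              config: ModelConfig | None = None,
              seed: int = 0) -> ModelPerformance:
    """Nested validation: repeated stratified 80/20 splits, inner tuning.

    Per outer iteration the hyperparameter is tuned on the training
    portion only and AUC / sensitivity / specificity are measured on the
    held-out portion; medians summarize the distributions.  A split that
    loses a class is resampled with a fresh seed (and logged).
    """
    if outer_iters < 1:
        raise ValueError("outer_iters must be >= 1")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    config = config or ModelConfig()
    X, y, names, _ = _prepare(table, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("nested validation requires both classes")
    rng = np.random.default_rng(seed)
    perf = ModelPerformance([], [], [], [])
    for it in range(outer_iters):
        for attempt in range(20):
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, test_size=test_fraction, stratify=y,
                random_state=int(rng.integers(2**31)))
            if len(np.unique(ytr)) == 2 and len(np.unique(yte)) == 2:
                break
            logger.warning("outer split %d lost a class; resampling", it)
        mtry, _ = _tune_mtry(Xtr, ytr, config, rng)
        forest = RandomForestClassifier(
            n_estimators=config.n_estimators, max_features=mtry,
            random_state=int(rng.integers(2**31)), n_jobs=1).fit(Xtr, ytr)
        prob = forest.predict_proba(Xte)[:, 1]
        fpr, tpr, auc = roc_points(prob, yte)
        sens, spec = _sens_spec(yte, prob, config.threshold)
        perf.auc.append(auc)
        perf.sensitivity.append(sens)
        perf.specificity.append(spec)
        perf.roc_curves.append((fpr, tpr))
    return perf


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_interactions(model: TrainedClassifier,
                         feature_table: pd.DataFrame) -> pd.DataFrame:
    """Classify pairs; pairs without any score are called non-interacting.

    All-missing rows bypass the forest entirely and get probability 0;
    the rest are scored by the forest and thresholded at the model's
    decision threshold.
    """
    X, usable, names = encode_features(feature_table)
    if names != model.feature_names:
        raise ValueError("feature columns do not match the trained model")
    prob = np.zeros(len(X))
    if usable.any():
        prob[usable] = model.decision_function(X[usable])
    label = np.where(usable & (prob >= model.threshold), POSITIVE, NEGATIVE)
    out = feature_table[["phage_id", "bacterium_id"]].copy() \
        if {"phage_id", "bacterium_id"} <= set(feature_table.columns) \
        else pd.DataFrame(index=feature_table.index)
    out["probability"] = prob
    out["prediction"] = label
    return out


# ---------------------------------------------------------------------------
# Feature importance
# ---------------------------------------------------------------------------

def feature_importance(model: TrainedClassifier, table: pd.DataFrame,
                       labels: Sequence | None = None, n_repeats: int = 10,
                       seed: int = 0, method: str | None = None,
                       ) -> pd.DataFrame:
    """Exclusion-style importance of the four evidence channels.

    Importance of a channel is the mean decrease in held-out accuracy
    when that channel is removed from the model's view.  The default
    estimator permutes the channel's column (jointly with its
    missingness indicator) in a held-out split, refitting on the rest;
    ``method="retrain"`` instead refits the forest without the channel.
    Returns per-channel mean, standard error and rank.
    """
    method = method or "permutation"
    if method not in ("permutation", "retrain"):
        raise ValueError(f"unknown importance method {method!r}")
    X, y, names, _ = _prepare(table, labels)
    n_feat = len(names) // 2
    rng = np.random.default_rng(seed)
    drops: dict[str, list[float]] = {names[i]: [] for i in range(n_feat)}
    for rep in range(n_repeats):
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=0.25, stratify=y,
            random_state=int(rng.integers(2**31)))
        base_forest = RandomForestClassifier(
            n_estimators=model.forest.n_estimators,
            max_features=model.mtry,
            random_state=int(rng.integers(2**31)), n_jobs=1).fit(Xtr, ytr)
        base_acc = float((base_forest.predict(Xte) == yte).mean())
        for i in range(n_feat):
            cols = [i, i + n_feat]  # channel + its missingness indicator
            if method == "permutation":
                Xp = Xte.copy()
                perm = rng.permutation(len(Xte))
                Xp[:, cols] = Xp[perm][:, cols]
                acc = float((base_forest.predict(Xp) == yte).mean())
            else:
                keep = [c for c in range(X.shape[1]) if c not in cols]
                f = RandomForestClassifier(
                    n_estimators=model.forest.n_estimators,
                    max_features=min(model.mtry, len(keep)),
                    random_state=int(rng.integers(2**31)),
                    n_jobs=1).fit(Xtr[:, keep], ytr)
                acc = float((f.predict(Xte[:, keep]) == yte).mean())
            drops[names[i]].append(base_acc - acc)
    rows = []
    for name, vals in drops.items():
        arr = np.asarray(vals)
        rows.append({"feature": name, "importance": float(arr.mean()),
                     "se": float(arr.std(ddof=1) / np.sqrt(len(arr)))
                     if len(arr) > 1 else 0.0})
    out = pd.DataFrame(rows).sort_values("importance", ascending=False,
                                         kind="stable")
    out["rank"] = range(1, len(out) + 1)
    return out.reset_index(drop=True)
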