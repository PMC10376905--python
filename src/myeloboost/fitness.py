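"""The tuning objective and the final classifier around it.

The quantity the metaheuristics maximize is the mean accuracy of a
gradient-boosted tree classifier (XGBoost) under stratified k-fold
cross-validation repeated several times (defaults: 10 folds x 3
repeats).  A candidate position in the search box decodes into the seven
XGBoost controls:

====================  =======================  =========================
name                  default search interval  meaning
====================  =======================  =========================
nrounds               [100, 600] (integer)     boosting iterations
eta_exponent          [-5, 0]                  log10 of the learning rate
max_depth             [2, 6] (integer)         tree depth
gamma                 [0, 1]                   min split loss reduction
colsample_bytree      [0.4, 1]                 feature fraction per tree
min_child_weight      [1, 3] (integer)         min hessian weight in leaf
subsample             [0.5, 1]                 row fraction per round
====================  =======================  =========================

The learning rate is searched on a log scale: the learner receives
``10 ** eta_exponent``.  The default exponent interval [-5, 0] spans the
whole usable range; a narrower [-5, -3] interval can be requested via
``search_space(eta_bounds=(-5, -3))``.

Class imbalance (benign variants outnumber pathogenic ~15:1) is handled
by a smoothed bootstrap of the minority class: resample minority rows
with replacement and perturb their continuous features with zero-mean
Gaussian noise (bandwidth per feature = Silverman's rule x a
configurable factor), leaving categorical codes and sentinel values
untouched.  By default oversampling happens after the train/test split
and only on the training side, so the test set keeps the original class
distribution.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import (RepeatedKFold, RepeatedStratifiedKFold,
                                     train_test_split)

from .codec import FEATURE_COLUMNS, LABEL_COLUMN
from .optimize import Dimension, SearchSpace

__all__ = [
    "Hyperparameters",
    "CVConfig",
    "SplitSpec",
    "search_space",
    "decode_hyperparameters",
    "stratified_split",
    "oversample_minority",
    "cv_accuracy_fitness",
    "make_objective",
    "train_final_model",
    "save_model",
    "load_model",
    "predict_scores",
    "feature_importance",
]

CODEC_VERSION = "1"

# scikit-learn >= 1.6 dropped the `_estimator_type` class attribute that
# xgboost's native save/load type check still expects; restore it.
if not hasattr(xgb.XGBClassifier, "_estimator_type"):
    xgb.XGBClassifier._estimator_type = "classifier"

# Features carrying continuous measurements; everything else in the
# vector is a categorical/ordinal code that oversampling must not smear.
_CONTINUOUS_FEATURES = ("POS", "Freq", "MAFbin", "Coverage")
# Features whose -1 is a sentinel, never to be jittered.
_SENTINEL_MINUS_ONE = ("MAFbin",)
_UNIT_INTERVAL = ("Freq", "MAFbin")


def search_space(eta_bounds: tuple[float, float] = (-5.0, 0.0),
                 ) -> SearchSpace:
    """The seven-dimensional XGBoost hyperparameter box."""
    return SearchSpace((
        Dimension("nrounds", 100, 600, integer=True),
        Dimension("eta_exponent", eta_bounds[0], eta_bounds[1]),
        Dimension("max_depth", 2, 6, integer=True),
        Dimension("gamma", 0.0, 1.0),
        Dimension("colsample_bytree", 0.4, 1.0),
        Dimension("min_child_weight", 1, 3, integer=True),
        Dimension("subsample", 0.5, 1.0),
    ))


@dataclasses.dataclass(frozen=True)
class Hyperparameters:
    nrounds: int
    eta_exponent: float
    max_depth: int
    gamma: float
    colsample_bytree: float
    min_child_weight: int
    subsample: float

    @property
    def learning_rate(self) -> float:
        return 10.0 ** self.eta_exponent

    def to_xgb_params(self, seed: int = 0) -> dict:
        return {
            "n_estimators": self.nrounds,
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            "gamma": self.gamma,
            "colsample_bytree": self.colsample_bytree,
            "min_child_weight": self.min_child_weight,
            "subsample": self.subsample,
            "n_jobs": 1,
            "tree_method": "hist",
            "random_state": seed,
            "eval_metric": "logloss",
        }

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class CVConfig:
    folds: int = 10
    repeats: int = 3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0
    oversample_stage: str = "after_split"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.oversample_stage not in ("after_split", "before_split"):
            raise ValueError("oversample_stage must be after_split|"
                             "before_split")


def decode_hyperparameters(position: np.ndarray,
                           space: SearchSpace) -> Hyperparameters:
    """Decode a continuous search position into learner controls.

    Integer-valued dimensions are rounded to the nearest integer; the
    search itself stays continuous.  Out-of-bounds positions are
    rejected - keeping candidates inside the box is the optimizer's job.
    """
    x = np.asarray(position, dtype=float)
    if not space.contains(x):
        raise ValueError(f"position {x} outside the search box")
    values: dict[str, float] = {}
    for dim, coord in zip(space.dims, x):
        values[dim.name] = int(round(coord)) if dim.integer else float(coord)
    return Hyperparameters(**values)  # type: ignore[arg-type]


def _require_label(table: pd.DataFrame) -> None:
    if LABEL_COLUMN not in table.columns:
        raise ValueError(f"table has no {LABEL_COLUMN!r} column")


def stratified_split(table: pd.DataFrame,
                     spec: SplitSpec = SplitSpec(),
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """70/30-style split preserving per-class proportions."""
    _require_label(table)
    labels = table[LABEL_COLUMN]
    if labels.nunique() < 2:
        raise ValueError("need both classes present to split")
    train, test = train_test_split(
        table, train_size=spec.train_fraction,
        stratify=labels if spec.stratified else None,
        random_state=spec.seed, shuffle=True)
    return (train.reset_index(drop=True), test.reset_index(drop=True))


def _silverman_bandwidth(values: np.ndarray) -> float:
    n = len(values)
    if n < 2:
        return 0.0
    sd = float(np.std(values, ddof=1))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale == 0.0:
        return 0.0
    return 0.9 * scale * n ** (-0.2)


def _snap_to_support(values: np.ndarray,
                     support: np.ndarray) -> np.ndarray:
    """Map each value to the nearest member of the observed support."""
    if len(support) == 0:
        return values
    idx = np.searchsorted(support, values)
    idx = np.clip(idx, 1, len(support) - 1) if len(support) > 1 else \
        np.zeros(len(values), dtype=int)
    if len(support) > 1:
        left = support[idx - 1]
        right = support[idx]
        idx = np.where(values - left <= right - values, idx - 1, idx)
    return support[idx]


def oversample_minority(train: pd.DataFrame, target_ratio: float = 1.0,
                        jitter: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Grow the minority class by smoothed bootstrap.

    Synthetic rows are resampled minority rows whose continuous features
    receive zero-mean Gaussian noise of width = Silverman bandwidth x
    ``jitter``, then snap to the nearest value observed among the
    donors, so every synthetic row carries valid feature values (genomic
    coordinates stay on real loci, frequencies keep their reporting
    resolution).  Categorical codes are copied unchanged, sentinel
    values (-1 codes) are never perturbed, and majority rows are
    untouched.
    """
    _require_label(train)
    counts = train[LABEL_COLUMN].value_counts()
    if len(counts) < 2:
        raise ValueError("need both classes present to oversample")
    minority_label = counts.idxmin()
    n_majority = int(counts.max())
    n_minority = int(counts.min())
    n_new = int(round(target_ratio * n_majority)) - n_minority
    if n_new <= 0:
        return train.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    minority = train[train[LABEL_COLUMN] == minority_label]
    picks = minority.iloc[rng.integers(0, n_minority, size=n_new)].copy()
    picks.reset_index(drop=True, inplace=True)
    for feature in _CONTINUOUS_FEATURES:
        if feature not in picks.columns or jitter == 0.0:
            continue
        donor = minority[feature].to_numpy(dtype=float)
        if feature in _SENTINEL_MINUS_ONE:
            donor = donor[donor != -1.0]
        width = jitter * _silverman_bandwidth(donor)
        if width == 0.0:
            continue
        values = picks[feature].to_numpy(dtype=float)
        jitterable = np.ones(len(values), dtype=bool)
        if feature in _SENTINEL_MINUS_ONE:
            jitterable = values != -1.0
        noise = rng.normal(0.0, width, size=len(values))
        values[jitterable] = values[jitterable] + noise[jitterable]
        if feature in _UNIT_INTERVAL:
            values[jitterable] = np.clip(values[jitterable], 0.0, 1.0)
        else:
            values[jitterable] = np.maximum(values[jitterable], 0.0)
        values[jitterable] = _snap_to_support(values[jitterable],
                                              np.unique(donor))
        picks[feature] = values
    out = pd.concat([train, picks], ignore_index=True)
    return out


def _xy(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    _require_label(table)
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks feature columns: {missing}")
    X = table.loc[:, list(FEATURE_COLUMNS)]
    y = table[LABEL_COLUMN].to_numpy(dtype=int)
    return X, y


def cv_accuracy_fitness(position: np.ndarray, space: SearchSpace,
                        table: pd.DataFrame,
                        cv: CVConfig = CVConfig(),
                        fit_callback: Optional[Callable[[], None]] = None,
                        ) -> float:
    """Mean held-out accuracy over folds x repeats partitions.

    Deterministic given (position, table contents, cv.seed): the table
    is canonically sorted before partitioning, so row order of the input
    does not matter.
    """
    hp = decode_hyperparameters(position, space)
    ordered = table.sort_values(by=list(FEATURE_COLUMNS) + [LABEL_COLUMN],
                                kind="mergesort").reset_index(drop=True)
    X, y = _xy(ordered)
    if cv.stratified:
        splitter = RepeatedStratifiedKFold(
            n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed)
    else:
        splitter = RepeatedKFold(
            n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed)
    accuracies = []
    try:
        for train_idx, test_idx in splitter.split(X, y):
            model = xgb.XGBClassifier(**hp.to_xgb_params(seed=cv.seed))
            model.fit(X.iloc[train_idx], y[train_idx])
            if fit_callback is not None:
                fit_callback()
            pred = model.predict(X.iloc[test_idx])
            accuracies.append(float(np.mean(pred == y[test_idx])))
    except Exception as exc:
        raise RuntimeError(f"learner failed with {hp.as_dict()}") from exc
    return float(np.mean(accuracies))


def make_objective(table: pd.DataFrame, space: SearchSpace,
                   cv: CVConfig = CVConfig()) -> Callable[[np.ndarray],
                                                          float]:
    """Bind a feature table and CV scheme into an optimizer objective."""
    def objective(position: np.ndarray) -> float:
        return cv_accuracy_fitness(position, space, table, cv)
    return objective


def train_final_model(train: pd.DataFrame, hp: Hyperparameters,
                      seed: int = 0) -> xgb.XGBClassifier:
    """Fit the classifier on the (balanced) training table."""
    X, y = _xy(train)
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    model = xgb.XGBClassifier(**hp.to_xgb_params(seed=seed))
    model.fit(X, y)
    return model


def save_model(model: xgb.XGBClassifier, path: str | Path,
               hp: Optional[Hyperparameters] = None) -> None:
    """Persist in the learner's native format + a sidecar JSON with the
    hyperparameters, feature names and codec version."""
    path = Path(path)
    model.save_model(path)
    sidecar = {
        "codec_version": CODEC_VERSION,
        "feature_names": list(FEATURE_COLUMNS),
        "hyperparameters": hp.as_dict() if hp is not None else None,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> xgb.XGBClassifier:
    model = xgb.XGBClassifier()
    model.load_model(Path(path))
    return model


def predict_scores(model: xgb.XGBClassifier,
                   features: pd.DataFrame) -> np.ndarray:
    """Pathogenicity probability per row (higher = more pathogenic)."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    extra = [c for c in features.columns
             if c not in FEATURE_COLUMNS and c != LABEL_COLUMN]
    if missing or extra:
        raise ValueError(f"feature columns mismatch: missing={missing} "
                         f"extra={extra}")
    if len(features) == 0:
        return np.empty(0, dtype=float)
    X = features.loc[:, list(FEATURE_COLUMNS)]
    if X.isna().to_numpy().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"NaN feature values in columns {bad}")
    return model.predict_proba(X)[:, 1]


def feature_importance(model: xgb.XGBClassifier,
                       method: str = "weight") -> pd.DataFrame:
    """Per-feature importance, normalized to sum to one.

    ``method="weight"`` (default) counts how often each feature is used
    to split across all trees; ``method="total_gain"`` reports each
    feature's share of the ensemble's total split gain instead.  A
    model with no splits at all yields a defined all-zero table.  The
    ``scaled_0_100`` column rescales so the top feature reads 100.
    """
    if method not in ("weight", "total_gain"):
        raise ValueError("method must be weight|total_gain")
    try:
        booster = model.get_booster()
    except Exception as exc:
        raise ValueError("model is not fitted") from exc
    raw = booster.get_score(importance_type=method)
    names = booster.feature_names or list(FEATURE_COLUMNS)
    counts = np.array([float(raw.get(name, 0.0)) for name in names])
    total = counts.sum()
    share = counts / total if total > 0 else counts
    top = share.max()
    scaled = 100.0 * share / top if top > 0 else share
    table = pd.DataFrame({"feature": names, "importance": share,
                          "scaled_0_100": scaled})
    return table.sort_values("importance", ascending=False,
                             ignore_index=True)
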