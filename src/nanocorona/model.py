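"""Imbalance-corrected ensemble-tree classification of corona membership.

The in-corona class is the minority (roughly 30% of proteins in the
training corpus this pipeline targets), so the training split is augmented
with SMOTE-synthesized minority points up to a 0.7:1 minority/majority
ratio (12 nearest neighbors) before fitting a 700-tree random forest with
the entropy split criterion.  Validation is a stratified shuffle split —
by default 100 repeats holding out 10% — scoring accuracy, ROC AUC,
precision and recall with the in-corona class positive, aggregated as the
mean with a percentile 95% confidence interval over splits.

SMOTE is applied to the training data only; a deliberate leakage mode
(oversampling before splitting) is retained for fidelity experiments and
must not be used for reported metrics.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedShuffleSplit, train_test_split
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SmoteConfig:
    """Minority oversampling settings (target ratio, neighborhood size)."""

    ratio: float = 0.7
    k_neighbors: int = 12
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio <= 1.0:
            raise ValueError(f"ratio must be in (0, 1], got {self.ratio}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be ≥ 1")


@dataclass(frozen=True)
class ClassifierConfig:
    """Ensemble-tree settings; the estimator kind is pluggable."""

    n_trees: int = 700
    split_criterion: str = "entropy"
    max_depth: int | None = None
    seed: int | None = None
    kind: str = "random_forest"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be ≥ 1")
        if self.split_criterion not in ("entropy", "gini"):
            raise ValueError(
                f"split_criterion must be entropy or gini, got "
                f"{self.split_criterion!r}"
            )


def _build_random_forest(cfg: ClassifierConfig) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion=cfg.split_criterion,
        max_depth=cfg.max_depth,
        random_state=cfg.seed,
        n_jobs=1,
    )


#: Pluggable estimator factories keyed by ClassifierConfig.kind.  Only the
#: ensemble-tree model ships; alternatives can be registered here.
CLASSIFIER_FACTORIES: dict[str, Callable[[ClassifierConfig], object]] = {
    "random_forest": _build_random_forest,
}


def smote(
    minority_vectors: np.ndarray, n_majority: int, cfg: SmoteConfig
) -> np.ndarray:
    """Synthesize minority-class points by k-NN interpolation.

    Each synthetic point is x_i + u·(x_j − x_i) with x_j one of the
    *k_neighbors* nearest minority neighbors of a random minority point x_i
    (Euclidean distance, intended for min-max-scaled space) and
    u ~ Uniform(0, 1).  Enough points are produced to bring the
    minority/majority ratio up to ``cfg.ratio``; if the ratio is already
    met, none are.
    """
    X = np.asarray(minority_vectors, dtype=float)
    n_minority = X.shape[0]
    if n_minority <= cfg.k_neighbors:
        raise ValueError(
            f"minority size {n_minority} must exceed k_neighbors="
            f"{cfg.k_neighbors}; use a smaller k"
        )
    n_target = math.ceil(cfg.ratio * n_majority)
    n_synth = max(0, n_target - n_minority)
    if n_synth == 0:
        return np.empty((0, X.shape[1]))
    rng = np.random.default_rng(cfg.seed)
    # +1 because the nearest neighbor of a point is itself
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(X)
    neighbor_idx = nn.kneighbors(X, return_distance=False)[:, 1:]
    base = rng.integers(n_minority, size=n_synth)
    pick = rng.integers(cfg.k_neighbors, size=n_synth)
    u = rng.uniform(size=n_synth)
    xi = X[base]
    xj = X[neighbor_idx[base, pick]]
    return xi + u[:, None] * (xj - xi)


def _augment(
    X: np.ndarray, y: np.ndarray, smote_cfg: SmoteConfig | None
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class of (X, y) with SMOTE."""
    if smote_cfg is None:
        return X, y
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    minority_label = n_pos <= n_neg
    X_min = X[y == minority_label]
    n_majority = max(n_pos, n_neg)
    synth = smote(X_min, n_majority, smote_cfg)
    if synth.shape[0] == 0:
        return X, y
    X_aug = np.vstack([X, synth])
    y_aug = np.concatenate(
        [y, np.full(synth.shape[0], minority_label, dtype=bool)]
    )
    return X_aug, y_aug


@dataclass
class CoronaClassifier:
    """A trained estimator plus the feature registry it was fit on.

    ``scaler`` optionally carries the min-max fit used to scale the
    training table, so persisted models can scale raw feature tables at
    prediction time.
    """

    estimator: object
    feature_names: list[str]
    cfg: ClassifierConfig
    smote_cfg: SmoteConfig | None
    scaler: object | None = None


def _as_matrix(features: pd.DataFrame) -> np.ndarray:
    return features.to_numpy(dtype=float)


def train(
    features: pd.DataFrame,
    labels: Sequence[bool],
    cfg: ClassifierConfig = ClassifierConfig(),
    smote_cfg: SmoteConfig | None = SmoteConfig(),
) -> CoronaClassifier:
    """Fit the classifier on (SMOTE-augmented) training data.

    ``features`` should already be min-max scaled; ``labels`` are booleans
    with True = in-corona.  Deterministic given the seeds in both configs.
    """
    if features.shape[1] == 0:
        raise ValueError("empty feature set")
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training labels contain a single class")
    X, y_aug = _augment(_as_matrix(features), y, smote_cfg)
    if cfg.kind not in CLASSIFIER_FACTORIES:
        raise ValueError(f"unknown classifier kind {cfg.kind!r}")
    est = CLASSIFIER_FACTORIES[cfg.kind](cfg)
    est.fit(X, y_aug)
    return CoronaClassifier(
        estimator=est,
        feature_names=list(features.columns),
        cfg=cfg,
        smote_cfg=smote_cfg,
    )


def predict_corona(
    model: CoronaClassifier, features: pd.DataFrame
) -> pd.DataFrame:
    """In-corona probability and call per protein.

    The probability is the fraction of trees voting in-corona; the call is
    in-corona iff probability ≥ 0.5 (inclusive).  Feature columns must
    match the training registry exactly.
    """
    missing = [c for c in model.feature_names if c not in features.columns]
    extra = [
        c for c in features.select_dtypes(include=[np.number]).columns
        if c not in model.feature_names
    ]
    if missing or extra:
        raise ValueError(
            f"feature registry mismatch: missing {missing}, extra {extra}"
        )
    X = _as_matrix(features[model.feature_names])
    classes = list(model.estimator.classes_)
    proba = model.estimator.predict_proba(X)[:, classes.index(True)]
    return pd.DataFrame(
        {
            "probability": proba,
            "in_corona": proba >= 0.5,
        },
        index=features.index,
    )


@dataclass
class ValidationResult:
    """Per-split metrics with mean and percentile 95% CI aggregates."""

    metrics: dict[str, list[float]]
    n_splits: int
    test_fraction: float

    METRIC_NAMES = ("accuracy", "auc", "precision", "recall")

    def _finite(self, name: str) -> np.ndarray:
        vals = np.asarray(self.metrics[name], dtype=float)
        return vals[~np.isnan(vals)]

    def mean(self, name: str) -> float:
        return float(self._finite(name).mean())

    def ci95(self, name: str) -> tuple[float, float]:
        vals = self._finite(name)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))

    def summary(self) -> dict:
        out: dict = {
            "n_splits": self.n_splits,
            "test_fraction": self.test_fraction,
        }
        for name in self.METRIC_NAMES:
            lo, hi = self.ci95(name)
            out[name] = {"mean": self.mean(name), "ci95": [lo, hi]}
        return out

    def to_json(self, path: str | Path) -> None:
        payload = self.summary()
        payload["per_split"] = {
            k: list(map(float, v)) for k, v in self.metrics.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _score_split(
    model: CoronaClassifier,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    metrics: dict[str, list[float]],
) -> None:
    pred = predict_corona(model, X_test)
    proba = pred["probability"].to_numpy()
    y_hat = pred["in_corona"].to_numpy()
    metrics["accuracy"].append(accuracy_score(y_test, y_hat))
    if len(np.unique(y_test)) < 2:
        logger.warning("single-class test split; AUC recorded as missing")
        metrics["auc"].append(float("nan"))
    else:
        metrics["auc"].append(roc_auc_score(y_test, proba))
    metrics["precision"].append(
        precision_score(y_test, y_hat, pos_label=True, zero_division=0)
    )
    metrics["recall"].append(
        recall_score(y_test, y_hat, pos_label=True, zero_division=0)
    )


def validate(
    features: pd.DataFrame,
    labels: Sequence[bool],
    n_splits: int = 100,
    test_fraction: float = 0.1,
    cfg: ClassifierConfig = ClassifierConfig(),
    smote_cfg: SmoteConfig | None = SmoteConfig(),
    seed: int | None = None,
    smote_before_split: bool = False,
) -> ValidationResult:
    """Repeated stratified shuffle-split validation.

    Each repeat holds out a stratified random *test_fraction*, resets the
    classifier, trains on the remainder (with SMOTE applied to the training
    split only), and scores the four metrics on the held-out set.  A
    single-class test split leaves that split's AUC missing and excluded
    from aggregation.  ``smote_before_split=True`` is the leakage mode
    (oversampling before the split) kept for fidelity experiments only.
    """
    y = np.asarray(labels, dtype=bool)
    if min(int(y.sum()), int((~y).sum())) < 2:
        raise ValueError("each class needs ≥2 members for stratified splits")
    rng = np.random.default_rng(seed)
    X_all, y_all = features, y
    smote_train = smote_cfg
    if smote_before_split and smote_cfg is not None:
        X_mat, y_aug = _augment(
            _as_matrix(features),
            y,
            replace(smote_cfg, seed=int(rng.integers(_MAX_SEED))),
        )
        X_all = pd.DataFrame(X_mat, columns=features.columns)
        y_all = y_aug
        smote_train = None
        logger.warning("SMOTE applied before splitting: leakage mode")
    sss = StratifiedShuffleSplit(
        n_splits=n_splits,
        test_size=test_fraction,
        random_state=int(rng.integers(_MAX_SEED)),
    )
    metrics: dict[str, list[float]] = {
        name: [] for name in ValidationResult.METRIC_NAMES
    }
    for train_idx, test_idx in sss.split(_as_matrix(X_all), y_all):
        model_seed = int(rng.integers(_MAX_SEED))
        smote_seed = int(rng.integers(_MAX_SEED))
        split_smote = (
            replace(smote_train, seed=smote_seed)
            if smote_train is not None
            else None
        )
        model = train(
            X_all.iloc[train_idx],
            y_all[train_idx],
            replace(cfg, seed=model_seed),
            split_smote,
        )
        _score_split(model, X_all.iloc[test_idx], y_all[test_idx], metrics)
    return ValidationResult(
        metrics=metrics, n_splits=n_splits, test_fraction=test_fraction
    )


def cross_biofluid_validate(
    features_a: pd.DataFrame,
    labels_a: Sequence[bool],
    features_b: pd.DataFrame,
    labels_b: Sequence[bool],
    n_total: int,
    n_repeats: int = 100,
    cfg: ClassifierConfig = ClassifierConfig(),
    smote_cfg: SmoteConfig | None = SmoteConfig(),
    seed: int | None = None,
) -> ValidationResult:
    """Train on all of biofluid A, test on random subsets of biofluid B.

    The test fraction of B is scaled so each test set holds 10% of
    *n_total* proteins: f = 0.1 × n_total / n_B, capped at 1 (with a
    warning).  This keeps cross-biofluid test sets the same size as the
    mixed-biofluid case.
    """
    if len(features_a) == 0 or len(features_b) == 0:
        raise ValueError("both biofluid sets must be nonempty")
    y_b = np.asarray(labels_b, dtype=bool)
    f = 0.1 * n_total / len(features_b)
    if f > 1:
        logger.warning(
            "requested test fraction %.3f > 1; capped at the full set", f
        )
        f = 1.0
    rng = np.random.default_rng(seed)
    model = train(
        features_a,
        labels_a,
        replace(cfg, seed=int(rng.integers(_MAX_SEED))),
        (
            replace(smote_cfg, seed=int(rng.integers(_MAX_SEED)))
            if smote_cfg is not None
            else None
        ),
    )
    metrics: dict[str, list[float]] = {
        name: [] for name in ValidationResult.METRIC_NAMES
    }
    for _ in range(n_repeats):
        if f >= 1.0:
            test_idx = np.arange(len(features_b))
        else:
            _, test_idx = train_test_split(
                np.arange(len(features_b)),
                test_size=f,
                stratify=y_b,
                random_state=int(rng.integers(_MAX_SEED)),
            )
        _score_split(model, features_b.iloc[test_idx], y_b[test_idx], metrics)
    return ValidationResult(
        metrics=metrics, n_splits=n_repeats, test_fraction=f
    )


def grid_search(
    features: pd.DataFrame,
    labels: Sequence[bool],
    grid: Sequence[ClassifierConfig],
    objective: str = "precision",
    n_splits: int = 10,
    test_fraction: float = 0.1,
    smote_cfg: SmoteConfig | None = SmoteConfig(),
    seed: int | None = None,
) -> tuple[ClassifierConfig, pd.DataFrame]:
    """Score each candidate config by shuffle-split validation and return
    the one maximizing the mean objective, plus the full score table.

    Ties go to fewer trees, then shallower depth (unlimited depth counts
    as deepest).
    """
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    if objective not in ValidationResult.METRIC_NAMES:
        raise ValueError(
            f"unknown objective {objective!r}; choose from "
            f"{ValidationResult.METRIC_NAMES}"
        )
    rows = []
    for cfg in grid:
        result = validate(
            features,
            labels,
            n_splits=n_splits,
            test_fraction=test_fraction,
            cfg=cfg,
            smote_cfg=smote_cfg,
            seed=seed,
        )
        row = {name: result.mean(name)
               for name in ValidationResult.METRIC_NAMES}
        row.update(
            n_trees=cfg.n_trees,
            max_depth=cfg.max_depth,
            split_criterion=cfg.split_criterion,
        )
        rows.append((cfg, row))
    table = pd.DataFrame([r for _, r in rows])
    depth_key = lambda c: math.inf if c.max_depth is None else c.max_depth
    best_cfg, _ = max(
        rows,
        key=lambda item: (
            item[1][objective],
            -item[0].n_trees,
            -depth_key(item[0]),
        ),
    )
    return best_cfg, table


def save_model(model: CoronaClassifier, path: str | Path) -> None:
    """Persist the trained model (joblib) with a JSON sidecar recording the
    feature registry and configs."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "format_version": 1,
        "feature_names": model.feature_names,
        "classifier": {
            "kind": model.cfg.kind,
            "n_trees": model.cfg.n_trees,
            "split_criterion": model.cfg.split_criterion,
            "max_depth": model.cfg.max_depth,
            "seed": model.cfg.seed,
        },
        "smote": (
            {
                "ratio": model.smote_cfg.ratio,
                "k_neighbors": model.smote_cfg.k_neighbors,
                "seed": model.smote_cfg.seed,
            }
            if model.smote_cfg is not None
            else None
        ),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def load_model(path: str | Path) -> CoronaClassifier:
    model = joblib.load(path)
    if not isinstance(model, CoronaClassifier):
        raise ValueError(f"{path} does not contain a corona classifier")
    return model
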