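"""Classifier registry, training, persistence and hyperparameter search.

The default classifier is a random forest with the tuned hyperparameters
(250 trees, depth 40, log2 feature subsampling, min_samples_split 3, full
bootstrap samples).  Four reference classifiers (decision tree, SVM with
probability outputs, k-nearest neighbors, Gaussian naive Bayes) are kept in
the registry for protocol comparisons; their remaining hyperparameters are
library defaults recorded in the run manifest.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

#: tuned random-forest defaults
RF_DEFAULTS: dict[str, Any] = {
    "n_estimators": 250,
    "max_depth": 40,
    "max_features": "log2",
    "min_samples_split": 3,
    "max_samples": 1.0,
}

#: default hyperparameter grids for the random-forest search
DEFAULT_GRIDS: dict[str, list] = {
    "n_estimators": [10, 50, 100, 150, 200, 250, 300, 350, 400, 450, 500],
    "max_depth": [10, 20, 30, 40, 50, 60, 70, 80, 90, 100],
}

_REGISTRY = {
    "RF": (RandomForestClassifier, RF_DEFAULTS),
    "DT": (DecisionTreeClassifier, {}),
    "SVM": (SVC, {"probability": True}),
    "KNN": (KNeighborsClassifier, {}),
    "NB": (GaussianNB, {}),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """An algorithm name, hyperparameter overrides and a seed."""

    algorithm: str = "RF"
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def resolved_hyperparameters(self) -> dict[str, Any]:
        """Registry defaults with the spec's overrides applied."""
        if self.algorithm not in _REGISTRY:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {sorted(_REGISTRY)}"
            )
        _, defaults = _REGISTRY[self.algorithm]
        return {**defaults, **self.hyperparameters}

    def replace(self, **hyperparameters: Any) -> "ClassifierSpec":
        return ClassifierSpec(
            algorithm=self.algorithm,
            hyperparameters={**self.hyperparameters, **hyperparameters},
            seed=self.seed,
        )


@dataclass
class TrainedModel:
    """A fitted classifier plus the metadata needed to reuse it safely."""

    spec: ClassifierSpec
    estimator: Any
    feature_names: list[str]
    metadata: dict[str, Any] = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability for each row of X."""
        X = np.asarray(X)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature width {X.shape[1]} != model width {len(self.feature_names)}"
            )
        return self.estimator.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def make_classifier(spec: ClassifierSpec):
    """Instantiate an untrained estimator from a spec.

    Unknown algorithm names and hyperparameters unknown to the estimator are
    rejected.
    """
    if spec.algorithm not in _REGISTRY:
        raise ValueError(
            f"unknown algorithm {spec.algorithm!r}; choose from {sorted(_REGISTRY)}"
        )
    cls, _ = _REGISTRY[spec.algorithm]
    params = spec.resolved_hyperparameters()
    valid = cls().get_params()
    unknown = set(params) - set(valid)
    if unknown:
        raise ValueError(
            f"unknown hyperparameters for {spec.algorithm}: {sorted(unknown)}"
        )
    if "random_state" in valid:
        params.setdefault("random_state", spec.seed)
    return cls(**params)


def _checksum(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec | None = None,
    feature_names: Sequence[str] | None = None,
    metadata: dict[str, Any] | None = None,
) -> TrainedModel:
    """Fit a classifier; deterministic for a given spec seed."""
    spec = spec or ClassifierSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows but {y.shape[0]} labels")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training samples")
    if feature_names is not None and len(feature_names) != X.shape[1]:
        raise ValueError(
            f"{len(feature_names)} feature names for width-{X.shape[1]} matrix"
        )
    estimator = make_classifier(spec).fit(X, y)
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])
    ]
    meta = {
        "dataset_checksum": _checksum(X, y),
        "n_samples": int(X.shape[0]),
        "trained_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "hyperparameters": spec.resolved_hyperparameters(),
        "seed": spec.seed,
        **(metadata or {}),
    }
    return TrainedModel(spec=spec, estimator=estimator, feature_names=names, metadata=meta)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict[str, list] | None = None,
    folds: int = 10,
    seed: int = 0,
    spec: ClassifierSpec | None = None,
) -> tuple[ClassifierSpec, list[dict[str, Any]]]:
    """Exhaustive hyperparameter search scored by mean stratified-CV accuracy.

    Ties are broken in favor of the first-listed candidate combination.
    Returns the winning spec and the full score table.
    """
    grid = grid if grid is not None else dict(DEFAULT_GRIDS)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty with non-empty candidate lists")
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    base = spec or ClassifierSpec(seed=seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split = list(splitter.split(X, y))
    names = list(grid)
    table: list[dict[str, Any]] = []
    best_score, best_spec = -np.inf, None
    for combo in itertools.product(*(grid[n] for n in names)):
        candidate = base.replace(**dict(zip(names, combo)))
        accs = []
        for train_idx, test_idx in split:
            est = make_classifier(candidate).fit(X[train_idx], y[train_idx])
            accs.append(float(np.mean(est.predict(X[test_idx]) == y[test_idx])))
        score = float(np.mean(accs))
        table.append({**dict(zip(names, combo)), "mean_accuracy": score})
        if score > best_score:  # strict: earlier candidates win ties
            best_score, best_spec = score, candidate
    return best_spec, table


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model archive plus a JSON metadata sidecar."""
    path = Path(path)
    joblib.dump(
        {"spec": model.spec, "estimator": model.estimator,
         "feature_names": model.feature_names, "metadata": model.metadata},
        path,
    )
    sidecar = {
        "algorithm": model.spec.algorithm,
        "hyperparameters": model.spec.resolved_hyperparameters(),
        "seed": model.spec.seed,
        "feature_names": model.feature_names,
        "metadata": {k: v for k, v in model.metadata.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str) + "\n"
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    return TrainedModel(
        spec=payload["spec"],
        estimator=payload["estimator"],
        feature_names=payload["feature_names"],
        metadata=payload["metadata"],
    )
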