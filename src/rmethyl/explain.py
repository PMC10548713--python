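"""Shapley-value attribution of trained site classifiers.

Attributions target the positive-class probability: for every explained
window, ``base_value + sum(attributions)`` equals the model's predicted
probability (local accuracy), where the base value is the mean prediction
over a background set drawn from the training matrix.

Two estimators are provided behind one entry point:

* tree ensembles (random forest, decision tree) get *exact* interventional
  Shapley values computed by a tree-traversal kernel, so local accuracy
  holds to float precision;
* any other probabilistic classifier gets a seeded permutation estimator,
  which still satisfies local accuracy exactly (each permutation's marginal
  contributions telescope) but is only stochastically exact per feature.

Global summaries follow the usual reading of such explanations: features
ranked by mean absolute attribution, block membership tallies of the top-k,
and per-feature (value, attribution) pairs for beeswarm-style summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from ._treeshap import tree_ensemble_shap
from .models import TrainedModel

_TREE_MODELS = (RandomForestClassifier, DecisionTreeClassifier)


@dataclass
class AttributionMatrix:
    """Per-sample per-feature Shapley values for one explained matrix."""

    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    feature_names: list[str]
    predictions: np.ndarray  # positive-class probability per sample
    background: dict[str, Any] = field(default_factory=dict)

    def local_accuracy_error(self) -> float:
        """max over samples of |base + sum(attributions) - prediction|."""
        recon = self.base_value + self.values.sum(axis=1)
        return float(np.max(np.abs(recon - self.predictions)))


@dataclass
class FeatureRanking:
    """Features ordered by mean absolute attribution."""

    ranking: list[tuple[str, float]]  # (feature name, mean |attribution|)
    block_tally: dict[str, int]  # top-k membership counts per block
    k: int


def sample_background(X: np.ndarray, size: int = 100, seed: int = 0) -> np.ndarray:
    """A seeded background subsample (without replacement when possible)."""
    X = np.asarray(X, dtype=float)
    if len(X) <= size:
        return X.copy()
    rng = np.random.default_rng(seed)
    return X[rng.choice(len(X), size=size, replace=False)]


def _permutation_shap(predict, X, Z, seed: int, n_permutations: int) -> np.ndarray:
    """Seeded permutation Shapley estimate for an arbitrary scoring function.

    For one permutation the marginal contributions telescope from the
    background mean to the full prediction, so local accuracy is exact.
    """
    rng = np.random.default_rng(seed)
    n, d = X.shape
    phi = np.zeros((n, d))
    for _ in range(n_permutations):
        order = rng.permutation(d)
        for i in range(n):
            cur = Z.copy()
            prev = float(np.mean(predict(cur)))
            for f in order:
                cur[:, f] = X[i, f]
                new = float(np.mean(predict(cur)))
                phi[i, f] += new - prev
                prev = new
    return phi / n_permutations


def attribute(
    model: TrainedModel,
    X: np.ndarray,
    background: np.ndarray,
    seed: int = 0,
    algorithm: str = "auto",
    n_permutations: int = 20,
) -> AttributionMatrix:
    """Shapley attributions of the positive-class probability.

    ``algorithm`` is ``"tree"`` (exact, tree ensembles only),
    ``"permutation"`` (any model), or ``"auto"`` which picks the exact path
    for tree ensembles and falls back to permutation sampling otherwise.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(background, dtype=float)
    if Z.size == 0:
        raise ValueError("background must not be empty")
    if X.shape[1] != len(model.feature_names) or Z.shape[1] != len(model.feature_names):
        raise ValueError(
            f"width mismatch: X {X.shape[1]}, background {Z.shape[1]}, "
            f"model {len(model.feature_names)}"
        )
    is_tree = isinstance(model.estimator, _TREE_MODELS)
    if algorithm == "auto":
        algorithm = "tree" if is_tree else "permutation"
    if algorithm == "tree":
        if not is_tree:
            raise ValueError("exact tree attribution requires a tree-ensemble model")
        values = tree_ensemble_shap(model.estimator, X, Z)
    elif algorithm == "permutation":
        values = _permutation_shap(model.predict_proba, X, Z, seed, n_permutations)
    else:
        raise ValueError(f"unknown attribution algorithm {algorithm!r}")
    return AttributionMatrix(
        values=values,
        base_value=float(np.mean(model.predict_proba(Z))),
        feature_names=list(model.feature_names),
        predictions=model.predict_proba(X),
        background={"size": int(len(Z)), "seed": seed, "algorithm": algorithm,
                    "target": "positive-class probability"},
    )


def rank_features(attr: AttributionMatrix, k: int = 20) -> FeatureRanking:
    """Rank features by mean |attribution|, descending, ties by name."""
    if k > len(attr.feature_names):
        raise ValueError(f"k={k} exceeds feature count {len(attr.feature_names)}")
    means = np.mean(np.abs(attr.values), axis=0)
    order = sorted(zip(attr.feature_names, means), key=lambda t: (-t[1], t[0]))
    tally: dict[str, int] = {}
    for name, _ in order[:k]:
        block = name.split("_", 1)[0]
        tally[block] = tally.get(block, 0) + 1
    return FeatureRanking(ranking=[(n, float(v)) for n, v in order],
                          block_tally=tally, k=k)


def summary_table(attr: AttributionMatrix, X: np.ndarray, k: int = 20) -> pd.DataFrame:
    """Beeswarm-ready summary of the top-k features, one row per feature.

    Each row carries the per-sample feature values and attributions (as
    arrays) plus feature-value quartiles, enough to reproduce a summary
    plot externally.
    """
    X = np.asarray(X, dtype=float)
    ranking = rank_features(attr, k).ranking[:k]
    name_to_col = {n: i for i, n in enumerate(attr.feature_names)}
    rows = []
    for rank, (name, mean_abs) in enumerate(ranking, start=1):
        col = name_to_col[name]
        vals = X[:, col]
        rows.append({
            "feature": name,
            "rank": rank,
            "mean_abs_attribution": mean_abs,
            "value_q25": float(np.quantile(vals, 0.25)),
            "value_q50": float(np.quantile(vals, 0.50)),
            "value_q75": float(np.quantile(vals, 0.75)),
            "values": vals.copy(),
            "attributions": attr.values[:, col].copy(),
        })
    return pd.DataFrame(rows)


def write_attributions_tsv(attr: AttributionMatrix, path: str | Path,
                           sample_ids: Sequence[str] | None = None) -> None:
    """Export the samples x features attribution matrix as TSV."""
    index = pd.Index(sample_ids, name="sample_id") if sample_ids is not None else None
    df = pd.DataFrame(attr.values, columns=attr.feature_names, index=index)
    df.to_csv(path, sep="\t", index=sample_ids is not None)


def write_ranking_json(ranking: FeatureRanking, path: str | Path) -> None:
    payload = {
        "k": ranking.k,
        "block_tally": ranking.block_tally,
        "ranking": [{"feature": n, "mean_abs_attribution": v}
                    for n, v in ranking.ranking],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def plot_summary(attr: AttributionMatrix, X: np.ndarray, path: str | Path,
                 k: int = 20) -> None:
    """Optional beeswarm-style rendering helper (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = summary_table(attr, X, k)
    fig, ax = plt.subplots(figsize=(7, 0.35 * k + 1.5))
    rng = np.random.default_rng(0)
    for i, row in table.iterrows():
        y = k - 1 - i + rng.normal(0, 0.07, size=len(row["attributions"]))
        ax.scatter(row["attributions"], y, c=row["values"], cmap="coolwarm",
                   s=8, alpha=0.7)
    ax.set_yticks(range(k))
    ax.set_yticklabels(reversed(table["feature"].tolist()))
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("Shapley value (positive-class probability)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
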