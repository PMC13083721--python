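"""Uniform introspection layer over trained bagged tree ensembles.

UbiQTree treats every tree of a bagged ensemble as one hypothesis about
feature attributions.  This module exposes the minimal view of an ensemble
the rest of the pipeline needs — per-tree node structure, per-tree
predictions, class labels, and (when recoverable) per-tree bootstrap
membership — plus the per-tree out-of-bag (OOB) reliability weights that
parameterize the Dirichlet base measure.

Supported sources:

* an in-memory scikit-learn ``RandomForestClassifier`` (or any forest of
  ``DecisionTreeClassifier`` built with bootstrap resampling);
* a JSON tree dump: a list of trees, each a node table with columns
  ``node_id, feature, threshold, left, right, leaf_values``.

Split convention everywhere: ``x[feature] <= threshold`` goes left.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.utils import check_random_state

__all__ = [
    "TreeView",
    "EnsembleView",
    "TreeWeights",
    "compute_per_tree_oob_accuracy",
    "softmax_weights",
]

#: sentinel used in the ``feature`` array for leaf nodes
LEAF = -1


@dataclass
class TreeView:
    """A single decision tree as flat node arrays.

    Arrays are indexed by node id; the root is node 0.  ``feature[i] == -1``
    marks a leaf; for internal nodes ``left``/``right`` hold child ids and
    the split sends ``x[feature] <= threshold`` left.  ``values`` holds one
    score vector per node (only leaf rows are used for prediction); for
    classifiers these are per-class probabilities.
    """

    feature: np.ndarray  # (n_nodes,) int, -1 for leaves
    threshold: np.ndarray  # (n_nodes,) float
    left: np.ndarray  # (n_nodes,) int
    right: np.ndarray  # (n_nodes,) int
    values: np.ndarray  # (n_nodes, n_classes) float

    def __post_init__(self) -> None:
        self.feature = np.asarray(self.feature, dtype=np.intp)
        self.threshold = np.asarray(self.threshold, dtype=float)
        self.left = np.asarray(self.left, dtype=np.intp)
        self.right = np.asarray(self.right, dtype=np.intp)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tree leaf values must be finite")

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def leaf_index(self, X: np.ndarray) -> np.ndarray:
        """Leaf node id reached by each row of ``X``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0], dtype=np.intp)
        for i, x in enumerate(X):
            node = 0
            while self.feature[node] != LEAF:
                if x[self.feature[node]] <= self.threshold[node]:
                    node = self.left[node]
                else:
                    node = self.right[node]
            out[i] = node
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Per-class score vectors, shape (n_rows, n_classes)."""
        return self.values[self.leaf_index(X)]


@dataclass
class EnsembleView:
    """Introspectable trained bagged ensemble.

    ``bootstrap_masks`` (optional) is a (K, n_train) boolean array where
    ``True`` marks rows *in* tree k's bootstrap sample; out-of-bag rows for
    tree k are ``~bootstrap_masks[k]``.
    """

    trees: list[TreeView]
    classes: np.ndarray
    bootstrap_masks: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.trees) < 2:
            raise ValueError("an ensemble needs at least 2 trees")
        self.classes = np.asarray(self.classes)
        n_classes = len(self.classes)
        for k, t in enumerate(self.trees):
            if t.n_classes != n_classes:
                raise ValueError(
                    f"tree {k} predicts {t.n_classes} classes, expected {n_classes}"
                )
        if self.bootstrap_masks is not None:
            self.bootstrap_masks = np.asarray(self.bootstrap_masks, dtype=bool)
            if self.bootstrap_masks.shape[0] != len(self.trees):
                raise ValueError("one bootstrap mask per tree required")

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_features(self) -> int:
        used = [t.feature[t.feature >= 0] for t in self.trees]
        non_empty = [u for u in used if u.size]
        return int(max(u.max() for u in non_empty)) + 1 if non_empty else 0

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Ensemble mean of per-tree score vectors."""
        return np.mean([t.predict(X) for t in self.trees], axis=0)

    # -- ingestion ---------------------------------------------------------

    @classmethod
    def from_sklearn(cls, forest, n_train: int | None = None) -> "EnsembleView":
        """Wrap a fitted scikit-learn forest.

        When the forest was trained with ``bootstrap=True`` and ``n_train``
        (the number of training rows) is given, per-tree bootstrap membership
        is reconstructed by replaying the per-estimator RNG draw scikit-learn
        uses to form bootstrap samples: ``randint(0, n, n)`` from the
        estimator's recorded ``random_state``.
        """
        trees = []
        for est in forest.estimators_:
            t = est.tree_
            vals = t.value[:, 0, :].copy()
            row_sums = vals.sum(axis=1, keepdims=True)
            vals = np.divide(vals, row_sums, out=np.zeros_like(vals), where=row_sums > 0)
            trees.append(
                TreeView(
                    feature=np.where(t.children_left == -1, LEAF, t.feature),
                    threshold=t.threshold,
                    left=t.children_left,
                    right=t.children_right,
                    values=vals,
                )
            )
        masks = None
        if getattr(forest, "bootstrap", False) and n_train is not None:
            n_boot = n_train
            if getattr(forest, "max_samples", None) is not None:
                ms = forest.max_samples
                n_boot = int(round(ms * n_train)) if isinstance(ms, float) else int(ms)
            masks = np.zeros((len(forest.estimators_), n_train), dtype=bool)
            for k, est in enumerate(forest.estimators_):
                rng = check_random_state(est.random_state)
                idx = rng.randint(0, n_train, n_boot)
                masks[k, idx] = True
        return cls(trees=trees, classes=np.asarray(forest.classes_), bootstrap_masks=masks)

    @classmethod
    def from_json(cls, path_or_obj) -> "EnsembleView":
        """Load from the documented JSON tree-dump format."""
        if isinstance(path_or_obj, (str, bytes)) or hasattr(path_or_obj, "__fspath__"):
            with open(path_or_obj) as fh:
                obj = json.load(fh)
        else:
            obj = path_or_obj
        trees = [_tree_from_node_table(td) for td in obj["trees"]]
        masks = np.asarray(obj["bootstrap_masks"], dtype=bool) if obj.get("bootstrap_masks") else None
        return cls(trees=trees, classes=np.asarray(obj["classes"]), bootstrap_masks=masks)

    def to_json(self, path) -> None:
        obj = {
            "classes": np.asarray(self.classes).tolist(),
            "trees": [
                [
                    {
                        "node_id": int(i),
                        "feature": int(t.feature[i]),
                        "threshold": float(t.threshold[i]),
                        "left": int(t.left[i]) if t.feature[i] != LEAF else -1,
                        "right": int(t.right[i]) if t.feature[i] != LEAF else -1,
                        "leaf_values": t.values[i].tolist(),
                    }
                    for i in range(len(t.feature))
                ]
                for t in self.trees
            ],
            "bootstrap_masks": self.bootstrap_masks.tolist() if self.bootstrap_masks is not None else None,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def _tree_from_node_table(node_table: Sequence[dict]) -> TreeView:
    n = len(node_table)
    feature = np.full(n, LEAF, dtype=np.intp)
    threshold = np.zeros(n)
    left = np.zeros(n, dtype=np.intp)
    right = np.zeros(n, dtype=np.intp)
    values = None
    for row in node_table:
        try:
            i = int(row["node_id"])
            f = int(row["feature"])
            if values is None:
                values = np.zeros((n, len(np.atleast_1d(row["leaf_values"]))))
            values[i] = row["leaf_values"]
            feature[i] = f
            threshold[i] = row["threshold"]
            if f != LEAF:
                left[i], right[i] = int(row["left"]), int(row["right"])
                if not (0 <= left[i] < n and 0 <= right[i] < n):
                    raise ValueError("child id out of range")
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed node table at node {row.get('node_id')}: {exc}") from exc
    return TreeView(feature, threshold, left, right, values)


@dataclass
class TreeWeights:
    """Per-tree OOB reliability and the softmax simplex weights built from it."""

    oob_accuracy: np.ndarray
    softmax: np.ndarray
    beta: float
    warnings: list[str] = field(default_factory=list)


def compute_per_tree_oob_accuracy(
    ensemble: EnsembleView,
    X: np.ndarray,
    y: np.ndarray,
    holdout: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Per-tree out-of-bag accuracy ``a_k``.

    For each tree, accuracy is the fraction of rows *outside* its bootstrap
    sample it classifies correctly (argmax of the score vector, lowest class
    index winning ties).  Without bootstrap masks a user-supplied
    ``holdout = (X_eval, y_eval)`` is required.  A tree whose OOB set is
    empty falls back to accuracy on the full ``(X, y)`` with a warning
    record.

    Returns ``(accuracies, warning_records)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("no evaluation data")
    if ensemble.bootstrap_masks is None and holdout is None:
        raise ValueError(
            "ensemble has no bootstrap masks; supply holdout=(X_eval, y_eval)"
        )

    class_index = {c: i for i, c in enumerate(ensemble.classes.tolist())}
    y_idx = np.asarray([class_index[v] for v in y.tolist()])

    recs: list[str] = []
    acc = np.empty(ensemble.n_trees)
    for k, tree in enumerate(ensemble.trees):
        if ensemble.bootstrap_masks is not None:
            oob = ~ensemble.bootstrap_masks[k]
            if oob.sum() == 0:
                recs.append(f"tree {k}: empty OOB set, falling back to full training data")
                warnings.warn(recs[-1], stacklevel=2)
                Xe, ye = X, y_idx
            else:
                Xe, ye = X[oob], y_idx[oob]
        else:
            Xh, yh = holdout
            Xe = np.atleast_2d(np.asarray(Xh, dtype=float))
            ye = np.asarray([class_index[v] for v in np.asarray(yh).tolist()])
        pred = np.argmax(tree.predict(Xe), axis=1)  # argmax -> lowest index on ties
        acc[k] = np.mean(pred == ye)
    return acc, recs


def softmax_weights(a: np.ndarray, beta: float) -> np.ndarray:
    """Simplex weights ``w_k = exp(beta * a_k) / sum_j exp(beta * a_j)``.

    Computed with max-subtraction for numerical stability; invariant to
    adding a constant to all accuracies, and uniform at ``beta = 0``.
    """
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("empty accuracy vector")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite accuracy")
    if beta < 0:
        raise ValueError("temperature beta must be nonnegative")
    z = beta * a
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def tree_weights(
    ensemble: EnsembleView,
    X: np.ndarray,
    y: np.ndarray,
    beta: float = 5.0,
    holdout=None,
) -> TreeWeights:
    """Convenience wrapper: OOB accuracies plus their softmax weights."""
    acc, recs = compute_per_tree_oob_accuracy(ensemble, X, y, holdout=holdout)
    return TreeWeights(oob_accuracy=acc, softmax=softmax_weights(acc, beta), beta=beta, warnings=recs)
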