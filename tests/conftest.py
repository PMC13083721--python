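"""Shared fixtures: hand-built forests with closed-form predictions and
out-of-bag sets, and small random tree generators for oracle checks."""

import numpy as np
import pytest

from ubiqtree.model_adapter import LEAF, TreeView
from ubiqtree.synthetic_data import make_fixture_forest


def stump_node_table(feature, threshold, left_vals, right_vals):
    """Node table of a one-split tree (root 0, leaves 1 and 2)."""
    return [
        {"node_id": 0, "feature": feature, "threshold": threshold,
         "left": 1, "right": 2, "leaf_values": [0.0] * len(left_vals)},
        {"node_id": 1, "feature": LEAF, "threshold": 0.0, "left": -1, "right": -1,
         "leaf_values": list(left_vals)},
        {"node_id": 2, "feature": LEAF, "threshold": 0.0, "left": -1, "right": -1,
         "leaf_values": list(right_vals)},
    ]


def leaf_node_table(vals):
    return [{"node_id": 0, "feature": LEAF, "threshold": 0.0, "left": -1,
             "right": -1, "leaf_values": list(vals)}]


@pytest.fixture
def ten_row_data():
    """x0 = -4..5 on feature 0 (second feature unused), y = 1 iff x0 > 0."""
    X = np.zeros((10, 2))
    X[:, 0] = np.arange(-4, 6)
    y = (X[:, 0] > 0).astype(int)
    return X, y


@pytest.fixture
def fixture_forest(ten_row_data):
    """Three hand-built trees over the ten-row data with hand-built masks.

    OOB accuracies countable by hand: tree 0 (perfect stump at 0) -> 1.0,
    tree 1 (stump at 1, misclassifies x0=1) -> 0.8 on its OOB rows,
    tree 2 (constant class-0 leaf) -> 0.4 on OOB rows {3..7} (2 of 5 are
    class 0).
    """
    masks = np.ones((3, 10), dtype=bool)
    masks[0, 5:] = False  # OOB rows 5..9: x0 = 1..5, all class 1
    masks[1, 4:9] = False  # OOB rows 4..8: x0 = 0..4
    masks[2, 3:8] = False  # OOB rows 3..7: x0 = -1..3
    return make_fixture_forest(
        {
            "trees": [
                stump_node_table(0, 0.0, [1.0, 0.0], [0.0, 1.0]),
                stump_node_table(0, 1.0, [1.0, 0.0], [0.0, 1.0]),
                leaf_node_table([1.0, 0.0]),
            ],
            "classes": [0, 1],
            "bootstrap_masks": masks,
        }
    )


def random_tree(d, depth, rng, n_classes=1, leaf_prob=0.3):
    """Random decision tree with random thresholds and leaf values."""
    feature, threshold, left, right, values = [], [], [], [], []

    def build(level):
        i = len(feature)
        if level == depth or rng.random() < leaf_prob:
            feature.append(LEAF)
            threshold.append(0.0)
            left.append(0)
            right.append(0)
            values.append(rng.normal(size=n_classes).tolist())
            return i
        feature.append(int(rng.integers(d)))
        threshold.append(float(rng.normal()))
        left.append(0)
        right.append(0)
        values.append([0.0] * n_classes)
        li = build(level + 1)
        ri = build(level + 1)
        left[i], right[i] = li, ri
        return i

    build(0)
    return TreeView(feature, threshold, left, right, values)
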