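"""Shapley attribution: brute-force oracle equivalence, local accuracy,
axiom checks, and sub-ensemble aggregation arithmetic."""

import numpy as np
import pytest

from ubiqtree.model_adapter import LEAF, TreeView
from ubiqtree.sampling import HypothesisSample
from ubiqtree.shap_core import (
    brute_force_shapley,
    constrained_treeshap,
    interventional_tree_shap,
    shap_tensor_for_samples,
    tree_shap,
)

from conftest import random_tree


def stump(feature, threshold, left, right, n_out=1):
    left = [left] if np.isscalar(left) else left
    right = [right] if np.isscalar(right) else right
    return TreeView(
        feature=[feature, LEAF, LEAF],
        threshold=[threshold, 0, 0],
        left=[1, 0, 0],
        right=[2, 0, 0],
        values=[[0.0] * len(left), list(left), list(right)],
    )


class TestBruteForceOracle:
    def test_additive_function_recovers_inputs(self):
        f = lambda rows: rows.sum(axis=1)
        x = np.array([1.5, -2.0, 0.5])
        B = np.zeros((4, 3))
        np.testing.assert_allclose(brute_force_shapley(f, x, B, 3), x, atol=1e-12)

    def test_symmetry_axiom(self):
        # exchangeable features (symmetric f, swap-closed background) with
        # equal instance values must get equal attributions
        f = lambda rows: rows[:, 0] * rows[:, 1] + rows[:, 0] + rows[:, 1]
        u = np.random.default_rng(0).normal(size=(4, 2))
        B = np.vstack([u, u[:, ::-1]])
        phi = brute_force_shapley(f, np.array([0.7, 0.7]), B, 2)
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)

    def test_product_of_binaries_hand_enumeration(self):
        f = lambda rows: rows[:, 0] * rows[:, 1]
        B = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        phi = brute_force_shapley(f, np.array([1.0, 1.0]), B, 2)
        np.testing.assert_allclose(phi, [0.375, 0.375])

    def test_large_d_rejected(self):
        with pytest.raises(ValueError, match="small d"):
            brute_force_shapley(lambda r: r.sum(1), np.zeros(13), np.zeros((2, 13)), 13)


class TestTreeShap:
    def test_single_split_stump(self):
        t = stump(0, 0.0, 0.0, 10.0)
        B = np.array([[-1.0, 0.0], [1.0, 0.0]])  # half the rows on each side
        phi, base = tree_shap(t, np.array([1.0, 0.0]), B)
        assert base[0] == pytest.approx(5.0)
        assert phi[0, 0] == pytest.approx(5.0)
        assert phi[1, 0] == pytest.approx(0.0)

    def test_constant_tree(self):
        t = TreeView([LEAF], [0.0], [0], [0], [[3.25]])
        phi, base = tree_shap(t, np.array([1.0, 2.0]), np.zeros((3, 2)))
        np.testing.assert_allclose(phi, 0.0)
        assert base[0] == pytest.approx(3.25)

    def test_depth_two_tree_matches_oracle(self):
        # splits on features {0, 1} with tabulated leaves, 4-row background
        t = TreeView(
            feature=[0, 1, 1, LEAF, LEAF, LEAF, LEAF],
            threshold=[0.0, -0.5, 0.5, 0, 0, 0, 0],
            left=[1, 3, 5, 0, 0, 0, 0],
            right=[2, 4, 6, 0, 0, 0, 0],
            values=[[0], [0], [0], [1.0], [2.0], [4.0], [8.0]],
        )
        B = np.array([[-1, -1], [-1, 1], [1, -1], [1, 1]], dtype=float)
        for x in ([-0.5, 0.3], [0.5, 0.7], [2.0, -2.0]):
            x = np.asarray(x)
            phi, base = tree_shap(t, x, B)
            phi_bf = brute_force_shapley(lambda r: t.predict(r)[:, 0], x, B, 2)
            np.testing.assert_allclose(phi[:, 0], phi_bf, atol=1e-8)
            assert phi[:, 0].sum() + base[0] == pytest.approx(t.predict(x[None])[0, 0])

    def test_oracle_equivalence_random_trees(self):
        """tree_shap equals exhaustive Shapley enumeration on random trees."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            d = int(rng.integers(2, 5))
            t = random_tree(d, depth=3, rng=rng)
            B = rng.normal(size=(int(rng.integers(2, 7)), d))
            for _ in range(5):
                x = rng.normal(size=d)
                phi, base = tree_shap(t, x, B)
                phi_bf = brute_force_shapley(lambda r: t.predict(r)[:, 0], x, B, d)
                np.testing.assert_allclose(phi[:, 0], phi_bf, atol=1e-8)

    def test_multiclass_local_accuracy(self):
        rng = np.random.default_rng(1)
        t = random_tree(4, depth=4, rng=rng, n_classes=3)
        B = rng.normal(size=(16, 4))
        X = rng.normal(size=(10, 4))
        phi, base = interventional_tree_shap(t, X, B)
        np.testing.assert_allclose(phi.sum(axis=1) + base, t.predict(X), atol=1e-10)

    def test_errors(self):
        t = stump(0, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="empty background"):
            tree_shap(t, np.zeros(2), np.empty((0, 2)))
        with pytest.raises(ValueError, match="mismatch"):
            tree_shap(t, np.zeros(3), np.zeros((2, 2)))


class TestConstrainedTreeShap:
    def make_sub(self, indices, K):
        pi = np.zeros(K)
        for i in indices:
            pi[i] += 1 / len(indices)
        return HypothesisSample(pi=pi, tree_indices=np.asarray(indices), sample_id=0)

    def test_same_tree_twice_zero_covariance(self, fixture_forest, ten_row_data):
        X, _ = ten_row_data
        sub = self.make_sub([0, 0], fixture_forest.n_trees)
        adj = constrained_treeshap(sub, fixture_forest, X[:3], X)
        np.testing.assert_allclose(adj.sigma, 0.0, atol=1e-12)
        np.testing.assert_allclose(adj.phi_adj, adj.phi_mean)

    @staticmethod
    def additive_indicator_tree(a, b):
        """Tree computing a*1[x0>0] + b*1[x1>0] via four leaves."""
        return TreeView(
            feature=[0, 1, 1, LEAF, LEAF, LEAF, LEAF],
            threshold=[0.0, 0.0, 0.0, 0, 0, 0, 0],
            left=[1, 3, 5, 0, 0, 0, 0],
            right=[2, 4, 6, 0, 0, 0, 0],
            values=[[0], [0], [0], [0.0], [b], [a], [a + b]],
        )

    def test_hand_arithmetic_two_tree_aggregation(self):
        # additive trees built so per-feature phi is [1, 3] and [3, 1] at
        # x=(1,1) over a quadrant-balanced background (each indicator
        # contributes half its amplitude): mean [2, 2], diag(Sigma) [1, 1]
        # (population convention), adjusted [2.5, 2.5]
        from ubiqtree.model_adapter import EnsembleView

        ens = EnsembleView(
            trees=[self.additive_indicator_tree(2.0, 6.0),
                   self.additive_indicator_tree(6.0, 2.0)],
            classes=[0],
        )
        B = np.array([[-1, -1], [-1, 1], [1, -1], [1, 1]], dtype=float)
        sub = HypothesisSample(pi=np.array([0.5, 0.5]), tree_indices=np.array([0, 1]), sample_id=0)
        adj = constrained_treeshap(sub, ens, np.array([[1.0, 1.0]]), B)
        np.testing.assert_allclose(adj.phi_per_tree[:, 0, :, 0], [[1, 3], [3, 1]], atol=1e-12)
        np.testing.assert_allclose(adj.phi_mean[0, :, 0], [2.0, 2.0])
        np.testing.assert_allclose(adj.sigma[0, [0, 1], [0, 1], 0], [1.0, 1.0])
        np.testing.assert_allclose(adj.phi_adj[0, :, 0], [2.5, 2.5])

    def test_local_accuracy_of_sub_ensemble_mean(self, fixture_forest, ten_row_data):
        X, _ = ten_row_data
        sub = self.make_sub([0, 1, 2, 1], fixture_forest.n_trees)
        adj = constrained_treeshap(sub, fixture_forest, X[2:6], X)
        sub_pred = np.mean(
            [fixture_forest.trees[k].predict(X[2:6]) for k in sub.tree_indices], axis=0
        )
        total = adj.phi_mean.sum(axis=1) + adj.base_per_tree.mean(axis=0)
        np.testing.assert_allclose(total, sub_pred, atol=1e-6)

    def test_adjustment_never_below_mean(self, fixture_forest, ten_row_data):
        X, _ = ten_row_data
        sub = self.make_sub([0, 1, 2], fixture_forest.n_trees)
        adj = constrained_treeshap(sub, fixture_forest, X, X)
        assert np.all(adj.phi_adj - adj.phi_mean >= -1e-12)

    def test_dummy_feature_has_zero_attribution(self, fixture_forest, ten_row_data):
        X, _ = ten_row_data  # feature 1 is never split on
        sub = self.make_sub([0, 1, 2], fixture_forest.n_trees)
        adj = constrained_treeshap(sub, fixture_forest, X, X)
        np.testing.assert_allclose(adj.phi_mean[:, 1, :], 0.0, atol=1e-12)
        np.testing.assert_allclose(adj.sigma[:, 1, 1, :], 0.0, atol=1e-12)


class TestShapTensor:
    def test_local_accuracy_every_cell(self, fixture_forest, ten_row_data):
        X, _ = ten_row_data
        samples = [
            HypothesisSample(pi=np.full(3, 1 / 3), tree_indices=np.array(ix), sample_id=i)
            for i, ix in enumerate([[0, 1], [2, 2], [1, 0]])
        ]
        tensor, _ = shap_tensor_for_samples(samples, fixture_forest, X[:4], X)
        S, T, n, d, c = tensor.values.shape
        for s in range(S):
            for t in range(T):
                tree = fixture_forest.trees[samples[s].tree_indices[t]]
                pred = tree.predict(X[:4])
                total = tensor.values[s, t].sum(axis=1) + tensor.base_values[s, t]
                np.testing.assert_allclose(total, pred, atol=1e-6)
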