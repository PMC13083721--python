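"""Exact interventional Shapley values for decision trees and sub-ensembles.

The attribution game for an instance ``x``, a tree ``f`` and a background
matrix ``B`` uses the interventional value function

    v(S) = mean over background rows b of f(x_S, b_{not S}),

i.e. features in the coalition ``S`` are fixed to the instance's values and
the rest take background values.  ``tree_shap`` computes the exact Shapley
values of this game in closed form by enumerating leaves rather than
coalitions:

For a fixed background row ``b`` and a leaf L, classify each feature that
appears on L's path (conditions on the same feature are intersected into
one interval per feature):

* both ``x`` and ``b`` satisfy the interval  -> irrelevant to reaching L;
* ``x`` satisfies, ``b`` does not           -> must be in S ("required");
* ``b`` satisfies, ``x`` does not           -> must be out of S ("forbidden");
* neither satisfies                         -> L unreachable, contributes 0.

The game restricted to one leaf is then a conjunction game whose Shapley
values have the closed form (r required, f forbidden features)

    phi_i = +leaf * (r-1)! f! / (r+f)!   for i required,
    phi_j = -leaf *  r! (f-1)! / (r+f)!  for j forbidden,

and the final attribution averages over background rows.  This is exact and
verified against ``brute_force_shapley``, an independent subset-enumeration
oracle, in the test suite.

Sub-ensemble attributions (``constrained_treeshap``) average per-tree values
over the tree slots of a hypothesis sample (a tree drawn twice counts
twice), record the between-tree feature covariance, and report the
interaction-adjusted attribution ``phi_adj = phi_mean + 0.5 * diag(Sigma)``.
All variances and covariances use the population (divide-by-n) convention so
the decomposition identities downstream hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

from scipy.special import gammaln

import numpy as np

from .model_adapter import LEAF, EnsembleView, TreeView
from .sampling import HypothesisSample

__all__ = [
    "ShapTensor",
    "AdjustedShap",
    "tree_shap",
    "interventional_tree_shap",
    "brute_force_shapley",
    "constrained_treeshap",
]

_MAX_ORACLE_FEATURES = 12


@dataclass
class ShapTensor:
    """Per (hypothesis sample, tree slot, instance, feature, class) SHAP values.

    ``base_values[s, t, c]`` is tree slot t's expected output over the
    background, so local accuracy reads
    ``values[s, t, n].sum(axis=feature) + base_values[s, t] = tree output``.
    """

    values: np.ndarray  # (S, T, n, d, c)
    base_values: np.ndarray  # (S, T, c)
    feature_names: list[str]
    class_names: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)) or not np.all(np.isfinite(self.base_values)):
            raise ValueError("ShapTensor entries must be finite")


@dataclass
class AdjustedShap:
    """Sub-ensemble attribution summary from one hypothesis sample."""

    phi_mean: np.ndarray  # (n, d, c)
    sigma: np.ndarray  # (n, d, d, c) between-tree feature covariance
    phi_adj: np.ndarray  # (n, d, c) = phi_mean + 0.5 * diag(sigma)
    phi_per_tree: np.ndarray  # (T, n, d, c)
    base_per_tree: np.ndarray  # (T, c)


def _leaf_paths(tree: TreeView):
    """Enumerate leaves with per-feature interval constraints.

    Yields ``(leaf_id, features, lo, hi)`` where the leaf is reached iff
    ``lo[p] < x[features[p]] <= hi[p]`` for every p.  Repeated splits on one
    feature along the path are intersected into a single interval.
    """
    stack = [(0, {})]
    while stack:
        node, bounds = stack.pop()
        f = tree.feature[node]
        if f == LEAF:
            feats = np.fromiter(bounds.keys(), dtype=np.intp, count=len(bounds))
            lo = np.array([bounds[k][0] for k in feats], dtype=float)
            hi = np.array([bounds[k][1] for k in feats], dtype=float)
            yield node, feats, lo, hi
            continue
        thr = tree.threshold[node]
        f = int(f)
        l, h = bounds.get(f, (-np.inf, np.inf))
        left_bounds = dict(bounds)
        left_bounds[f] = (l, min(h, thr))
        right_bounds = dict(bounds)
        right_bounds[f] = (max(l, thr), h)
        stack.append((tree.left[node], left_bounds))
        stack.append((tree.right[node], right_bounds))


def _conjunction_weights(max_p: int):
    """Shapley weights of conjunction games, tabulated.

    ``wr[r, f] = (r-1)! f! / (r+f)!`` (marginal weight of a required
    feature) and ``wf[r, f] = r! (f-1)! / (r+f)!`` (of a forbidden one).
    Computed in log space so deep paths cannot overflow.
    """
    lg = gammaln(np.arange(2 * max_p + 2) + 1.0)  # lg[i] = log(i!)
    r = np.arange(max_p + 1)[:, None]
    f = np.arange(max_p + 1)[None, :]
    wr = np.where(r >= 1, np.exp(lg[np.maximum(r - 1, 0)] + lg[f] - lg[r + f]), 0.0)
    wf = np.where(f >= 1, np.exp(lg[r] + lg[np.maximum(f - 1, 0)] - lg[r + f]), 0.0)
    return wr, wf


def interventional_tree_shap(
    tree: TreeView, X: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact interventional Shapley values of one tree for many instances.

    Parameters
    ----------
    X : (n, d) instances to explain.
    B : (m, d) background matrix defining the interventional distribution.

    Returns
    -------
    phi : (n, d, n_classes) Shapley values.
    base : (n_classes,) expected tree output over the background; local
        accuracy ``phi[i].sum(axis=0) + base == tree.predict(X[i])`` holds
        exactly for every instance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if B.shape[0] == 0:
        raise ValueError("empty background")
    if X.shape[1] != B.shape[1]:
        raise ValueError("instance/background feature-count mismatch")
    n, d = X.shape
    m = B.shape[0]
    c = tree.n_classes
    phi = np.zeros((n, d, c))
    base = np.zeros(c)

    wr_tab, wf_tab = _conjunction_weights(min(d, len(tree.feature)) + 1)

    for leaf, feats, lo, hi in _leaf_paths(tree):
        val = tree.values[leaf]  # (c,)
        if feats.size == 0:  # root is a leaf: constant tree
            base += val
            continue
        Xok = (X[:, feats] > lo) & (X[:, feats] <= hi)  # (n, p)
        Bok = (B[:, feats] > lo) & (B[:, feats] <= hi)  # (m, p)
        base += val * Bok.all(axis=1).mean()

        req = Xok[:, None, :] & ~Bok[None, :, :]  # (n, m, p)
        forb = ~Xok[:, None, :] & Bok[None, :, :]
        alive = ~(~Xok[:, None, :] & ~Bok[None, :, :]).any(axis=2)  # (n, m)
        r = req.sum(axis=2)
        f = forb.sum(axis=2)
        wr = np.where(alive, wr_tab[r, f], 0.0)
        wf = np.where(alive, wf_tab[r, f], 0.0)
        # average contribution of this leaf over background rows
        c_req = np.einsum("nm,nmp->np", wr, req) / m
        c_forb = np.einsum("nm,nmp->np", wf, forb) / m
        phi[:, feats, :] += (c_req - c_forb)[:, :, None] * val[None, None, :]
    return phi, base


def tree_shap(tree: TreeView, x: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interventional Shapley values for one instance; see
    :func:`interventional_tree_shap`.

    Returns ``(phi, base)`` with ``phi`` of shape (d, n_classes).
    """
    phi, base = interventional_tree_shap(tree, np.atleast_2d(x), B)
    return phi[0], base


def brute_force_shapley(f, x: np.ndarray, B: np.ndarray, d: int) -> np.ndarray:
    """Exact Shapley values by subset enumeration — the independent oracle.

    ``f`` is any black-box ``(rows, d) -> scores`` function (scalar or
    per-class vector output).  The value function is the same interventional
    one as :func:`tree_shap`: coalition features come from ``x``, the rest
    from each background row, averaged over ``B``.  Efficiency
    ``sum(phi) = f(x) - v(empty)`` holds by construction.  Limited to
    ``d <= 12`` features (2^d coalitions).
    """
    if d > _MAX_ORACLE_FEATURES:
        raise ValueError("oracle limited to small d (<= 12 features)")
    x = np.asarray(x, dtype=float).ravel()
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if B.shape[0] == 0:
        raise ValueError("empty background")

    def v(S: tuple[int, ...]) -> np.ndarray:
        hybrid = B.copy()
        if S:
            hybrid[:, list(S)] = x[list(S)]
        return np.atleast_1d(np.mean(np.atleast_1d(f(hybrid)), axis=0))

    cache = {S: v(S) for size in range(d + 1) for S in combinations(range(d), size)}
    out_dim = cache[()].shape[0]
    phi = np.zeros((d, out_dim))
    for i in range(d):
        others = [j for j in range(d) if j != i]
        for size in range(d):
            w = 1.0 / (d * comb(d - 1, size))
            for S in combinations(others, size):
                Si = tuple(sorted(S + (i,)))
                phi[i] += w * (cache[Si] - cache[S])
    return phi[:, 0] if out_dim == 1 else phi


def constrained_treeshap(
    sub: HypothesisSample,
    ensemble: EnsembleView,
    X: np.ndarray,
    B: np.ndarray,
    per_tree_cache: dict[int, tuple[np.ndarray, np.ndarray]] | None = None,
) -> AdjustedShap:
    """Sub-ensemble SHAP for one hypothesis sample.

    Computes per-tree interventional Shapley values for every tree slot of
    the sample (multiplicity respected), their slot mean, the between-tree
    feature covariance per instance and class (population convention; the
    zero matrix for single-slot samples), and the interaction-adjusted
    attribution.  ``per_tree_cache`` maps tree index -> ``(phi, base)`` and
    is filled on demand so repeated tree indices — within this sample or
    across samples — are computed once.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("no instances to explain")
    if per_tree_cache is None:
        per_tree_cache = {}
    idx = np.asarray(sub.tree_indices, dtype=np.intp)
    if idx.min() < 0 or idx.max() >= ensemble.n_trees:
        raise ValueError("sub-ensemble references invalid trees")
    for k in np.unique(idx):
        if int(k) not in per_tree_cache:
            per_tree_cache[int(k)] = interventional_tree_shap(ensemble.trees[int(k)], X, B)

    phi_slots = np.stack([per_tree_cache[int(k)][0] for k in idx])  # (T, n, d, c)
    base_slots = np.stack([per_tree_cache[int(k)][1] for k in idx])  # (T, c)
    phi_mean = phi_slots.mean(axis=0)
    T = phi_slots.shape[0]
    centered = phi_slots - phi_mean  # (T, n, d, c)
    if T > 1:
        sigma = np.einsum("tnic,tnjc->nijc", centered, centered) / T
    else:
        n, d, c = phi_mean.shape
        sigma = np.zeros((n, d, d, c))
    diag = np.einsum("niic->nic", sigma)
    return AdjustedShap(
        phi_mean=phi_mean,
        sigma=sigma,
        phi_adj=phi_mean + 0.5 * diag,
        phi_per_tree=phi_slots,
        base_per_tree=base_slots,
    )


def shap_tensor_for_samples(
    samples: list[HypothesisSample],
    ensemble: EnsembleView,
    X: np.ndarray,
    B: np.ndarray,
    feature_names: list[str] | None = None,
    class_names: list[str] | None = None,
) -> tuple[ShapTensor, list[AdjustedShap]]:
    """Materialize the full SHAP tensor over hypothesis samples.

    All samples must share one ``n_draw`` so tree slots align.  Per-tree
    values are cached across samples: each distinct tree of the parent
    ensemble is explained once regardless of how often it is drawn.
    """
    cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    per_sample = [constrained_treeshap(s, ensemble, X, B, per_tree_cache=cache) for s in samples]
    values = np.stack([a.phi_per_tree for a in per_sample])  # (S, T, n, d, c)
    bases = np.stack([a.base_per_tree for a in per_sample])  # (S, T, c)
    d, c = values.shape[3], values.shape[4]
    tensor = ShapTensor(
        values=values,
        base_values=bases,
        feature_names=feature_names or [f"x{i}" for i in range(d)],
        class_names=class_names or [str(i) for i in range(c)],
    )
    return tensor, per_sample
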