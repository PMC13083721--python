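"""Dirichlet-process hypothesis sampling over ensemble trees.

A trained bagged ensemble is read as a finite hypothesis space: each tree is
one plausible account of how features drive the prediction.  The posterior
over sub-ensembles is modelled by a Dirichlet distribution whose parameter
vector is ``alpha * w``, where ``w`` are the OOB-reliability softmax weights
(the discrete base measure) and ``alpha`` the concentration.  Each hypothesis
sample draws simplex weights ``pi ~ Dirichlet(alpha * w)`` and then a
multiset of tree indices i.i.d. from ``Categorical(pi)``.

Concentration behaviour follows the Dirichlet mathematics: ``E[pi] = w`` for
every ``alpha``; small ``alpha`` concentrates each draw's mass on few trees
(low effective diversity per sub-ensemble), large ``alpha`` makes every draw
hug the base measure ``w``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SamplingConfig", "HypothesisSample", "dirichlet_sample", "effective_diversity"]

#: floor applied to Dirichlet parameters before drawing (gamma-sampler stability)
PARAM_FLOOR = 1e-8


@dataclass
class SamplingConfig:
    """Hypothesis-sampling configuration.

    alpha : Dirichlet concentration (> 0).
    beta : softmax temperature used upstream to build ``w`` (>= 0).
    n_samples : number of hypothesis samples S (>= 2).
    n_draw : trees per sub-ensemble, sampled with replacement; ``None``
        means K (the ensemble size), the Bayesian-bootstrap scale.
    seed : root seed; each sample gets its own spawned substream so that
        growing ``n_samples`` never perturbs earlier samples.
    """

    alpha: float = 0.5
    beta: float = 5.0
    n_samples: int = 30
    n_draw: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.n_samples < 2:
            raise ValueError("need at least 2 hypothesis samples")
        if self.n_draw is not None and self.n_draw < 1:
            raise ValueError("n_draw must be >= 1")


@dataclass
class HypothesisSample:
    """One Dirichlet draw: simplex weights and the sub-ensemble it induced."""

    pi: np.ndarray
    tree_indices: np.ndarray
    sample_id: int
    seed_state: tuple = field(default=())

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.tree_indices = np.asarray(self.tree_indices, dtype=np.intp)
        if abs(self.pi.sum() - 1.0) > 1e-9 or np.any(self.pi < 0):
            raise ValueError("pi must lie on the probability simplex")
        if self.tree_indices.size and (
            self.tree_indices.min() < 0 or self.tree_indices.max() >= self.pi.size
        ):
            raise ValueError("tree index out of range")


def dirichlet_sample(w: np.ndarray, config: SamplingConfig) -> list[HypothesisSample]:
    """Draw ``config.n_samples`` hypothesis-consistent sub-ensembles.

    Reproducible from ``config.seed``: sample ``s`` always uses substream
    ``s`` of the root seed sequence, independent of ``n_samples``.
    """
    w = np.asarray(w, dtype=float)
    K = w.size
    if K < 2:
        raise ValueError("need at least 2 trees to sample sub-ensembles")
    if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
        raise ValueError("w must lie on the probability simplex")
    conc = np.maximum(config.alpha * w, PARAM_FLOOR)
    if np.all(config.alpha * w < PARAM_FLOOR):
        raise ValueError("degenerate concentration: all alpha * w below floor")
    n_draw = config.n_draw if config.n_draw is not None else K

    root = np.random.SeedSequence(config.seed)
    out = []
    for s, child in enumerate(root.spawn(config.n_samples)):
        rng = np.random.default_rng(child)
        pi = rng.dirichlet(conc)
        idx = rng.choice(K, size=n_draw, replace=True, p=pi)
        out.append(
            HypothesisSample(pi=pi, tree_indices=idx, sample_id=s, seed_state=tuple(child.entropy) if isinstance(child.entropy, (list, tuple)) else (child.entropy, s))
        )
    return out


def effective_diversity(samples: list[HypothesisSample]) -> np.ndarray:
    """Effective number of distinct trees per sample.

    ``exp`` of the Shannon entropy of the empirical tree-index frequencies;
    ranges from 1 (one tree repeated) to K (all indices distinct and
    equally frequent).  A diagnostic for how ``alpha`` trades exploration
    against concentration on high-weight trees.
    """
    if not samples:
        raise ValueError("no samples")
    out = np.empty(len(samples))
    for i, s in enumerate(samples):
        _, counts = np.unique(s.tree_indices, return_counts=True)
        p = counts / counts.sum()
        out[i] = np.exp(-np.sum(p * np.log(p)))
    return out
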