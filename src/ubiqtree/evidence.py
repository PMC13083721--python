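"""Dempster-Shafer and uncertainty-distribution layers over SHAP samples.

The observed range of a feature's SHAP values is partitioned into M
equal-width cells (the frame of discernment).  Each evidence source — a
hypothesis-sampled sub-ensemble — contributes mass ``1/n_sources`` to the
*set* of cells its per-tree SHAP values hit: a source whose trees agree
(all values in one cell) yields crisp singleton evidence, a dispersed
source yields genuinely set-valued evidence with belief strictly below
plausibility.  Belief is the mass of focal elements contained in a query
set, plausibility the mass of those intersecting it, and the per-feature
conflict is the largest plausibility-belief gap over single cells —
the degree to which the ensemble's explanations are ambiguous rather than
merely spread out.

The second layer is the uncertainty distribution Γ: the empirical CDF of
the SHAP samples, which is 0 below the observed minimum, 1 at the maximum,
monotone nondecreasing, and crosses 0.5 at the median.  Its entropy (the
differential entropy of dΓ/dc, estimated with the same boundary-corrected
KDE as the aggregation layer) summarizes explanation spread, and the
variance-first acquisition ranking orders features by where additional
data would most reduce that entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .aggregation import DEGENERATE_ENTROPY, entropy_estimate

__all__ = [
    "Partition",
    "MassFunction",
    "GammaDistribution",
    "build_partition",
    "build_bpa",
    "belief",
    "plausibility",
    "conflict",
    "uncertainty_cdf",
    "gamma_entropy",
    "acquisition_ranking",
]


@dataclass
class Partition:
    """Equal-width cells over the observed SHAP range.

    ``edges`` has M+1 entries; cell j is ``[edges[j], edges[j+1])`` with the
    last cell closed on the right.
    """

    edges: np.ndarray
    degenerate: bool = False

    @property
    def n_cells(self) -> int:
        return len(self.edges) - 1

    def cell_of(self, values: np.ndarray, clamp_warn: bool = True) -> np.ndarray:
        """Cell index per value; out-of-range values clamp to the nearest
        cell with a warning."""
        v = np.asarray(values, dtype=float)
        lo, hi = self.edges[0], self.edges[-1]
        if clamp_warn and (np.any(v < lo) or np.any(v > hi)):
            warnings.warn("SHAP value outside partition range; clamping to nearest cell", stacklevel=2)
        if self.degenerate:
            return np.zeros(v.shape, dtype=np.intp)
        idx = np.searchsorted(self.edges, v, side="right") - 1
        return np.clip(idx, 0, self.n_cells - 1)


@dataclass
class MassFunction:
    """Basic probability assignment: mass over focal elements (frozensets
    of cell indices).  Masses sum to one; the empty set carries none."""

    masses: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.masses.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"masses must sum to 1, got {total}")
        if any(len(fe) == 0 for fe in self.masses):
            raise ValueError("empty focal element not allowed")
        if any(m <= 0 for m in self.masses.values()):
            raise ValueError("focal masses must be positive")


@dataclass
class GammaDistribution:
    """Empirical uncertainty distribution of a SHAP sample set."""

    support: np.ndarray  # sorted observed values
    entropy: float
    entropy_degenerate: bool

    def __call__(self, c) -> np.ndarray | float:
        """Degree of belief that the SHAP value is <= c (empirical CDF)."""
        c = np.asarray(c, dtype=float)
        out = np.searchsorted(self.support, c, side="right") / self.support.size
        return float(out) if out.ndim == 0 else out


def build_partition(shap_samples: np.ndarray, M: int) -> Partition:
    """Partition the observed SHAP range into M equal-width cells.

    An all-equal sample yields a single-cell partition flagged degenerate.
    """
    if M < 2:
        raise ValueError("need at least 2 cells")
    v = np.asarray(shap_samples, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("no SHAP samples")
    lo, hi = v.min(), v.max()
    if lo == hi:
        return Partition(edges=np.array([lo, hi]), degenerate=True)
    return Partition(edges=np.linspace(lo, hi, M + 1))


def build_bpa(per_source_values: list[np.ndarray], partition: Partition) -> MassFunction:
    """Mass function from per-source SHAP value multisets.

    Each source contributes mass ``1/n_sources`` to the set of cells
    containing at least one of its values; single-cell sources reproduce
    the classical proportion-of-trees singleton assignment.
    """
    if len(per_source_values) == 0:
        raise ValueError("need at least one evidence source")
    w = 1.0 / len(per_source_values)
    masses: dict[frozenset, float] = {}
    for vals in per_source_values:
        cells = frozenset(partition.cell_of(np.asarray(vals)).tolist())
        masses[cells] = masses.get(cells, 0.0) + w
    return MassFunction(masses=masses)


def belief(m: MassFunction, A) -> float:
    """Total mass of focal elements contained in A."""
    A = frozenset(A)
    return sum(v for fe, v in m.masses.items() if fe <= A)


def plausibility(m: MassFunction, A) -> float:
    """Total mass of focal elements intersecting A."""
    A = frozenset(A)
    return sum(v for fe, v in m.masses.items() if fe & A)


def conflict(m: MassFunction, partition: Partition) -> float:
    """Explanation conflict: max over cells of Pl({j}) - Bel({j}).

    Zero for purely singleton (Bayesian) evidence; 1 when all mass sits on
    one multi-cell focal element.
    """
    gaps = [
        plausibility(m, {j}) - belief(m, {j}) for j in range(partition.n_cells)
    ]
    # float summation can stray a few ulp outside the unit interval
    return float(np.clip(max(gaps), 0.0, 1.0)) if gaps else 0.0


def uncertainty_cdf(shap_samples: np.ndarray) -> GammaDistribution:
    """Empirical uncertainty distribution Γ of a SHAP sample set."""
    v = np.sort(np.asarray(shap_samples, dtype=float).ravel())
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    if v[0] == v[-1] or v.size < 10:
        h, deg = DEGENERATE_ENTROPY, True
    else:
        h, deg = entropy_estimate(v)
    return GammaDistribution(support=v, entropy=h, entropy_degenerate=deg)


def gamma_entropy(g: GammaDistribution) -> float:
    """Entropy of the uncertainty density dΓ/dc (precomputed at build)."""
    return g.entropy


def acquisition_ranking(
    variances: np.ndarray, entropies: np.ndarray, names: list[str] | None = None
) -> list[int] | list[str]:
    """Order features by expected uncertainty-entropy reduction.

    Descending by SHAP variance (the entropy-reduction rate of additional
    data is proportional to it), ties broken by descending Γ-entropy.  The
    top entry is where new data buys the most certainty.
    """
    var = np.asarray(variances, dtype=float)
    ent = np.asarray(entropies, dtype=float)
    if var.size == 0:
        raise ValueError("need at least one feature")
    order = np.lexsort((-ent, -var))
    if names is not None:
        return [names[i] for i in order]
    return order.tolist()
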