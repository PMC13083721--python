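"""Aleatoric / epistemic / entanglement decomposition of SHAP variability.

Given per-tree SHAP values grouped by hypothesis sample, the within-sample
replicates are the per-tree values inside each sub-ensemble and the
between-sample units are the sub-ensemble means.  For each feature (and
class, and instance) with per-sample mean ``mu_s`` and per-sample variance
``sigma2_s``:

* aleatoric  A = mean_s(sigma2_s)          — irreducible between-tree spread,
* epistemic  E = Var_s(mu_s)               — spread of sub-ensemble means,
* entanglement C = Cov_s(mu_s, sigma2_s)   — coupling of importance & spread,

all in the population (divide-by-S) convention, with the reported total
``A + E - C``.  A positive C means hypothesis samples that attribute more
to a feature also disagree more about it internally, so the naive
``A + E`` sum overstates the combined variance.

The companion diagnostic :func:`entanglement_correlation` is the
feature-level analogue: the Pearson correlation, across features of one
class, between mean absolute SHAP (importance) and the standard deviation
of SHAP across hypothesis samples (explanation instability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "UncertaintyDecomposition",
    "EntanglementCorrelation",
    "decompose_variance",
    "entanglement_correlation",
]


@dataclass
class UncertaintyDecomposition:
    """Variance components; arrays share the trailing shape of the input
    (e.g. ``(features,)`` or ``(instances, features, classes)``)."""

    aleatoric: np.ndarray
    epistemic: np.ndarray
    entanglement: np.ndarray
    total: np.ndarray  # A + E - C
    mu_s: np.ndarray  # per-sample means, leading axis = sample
    sigma2_s: np.ndarray  # per-sample variances, leading axis = sample


@dataclass
class EntanglementCorrelation:
    """Importance-vs-instability Pearson correlation for one class."""

    rho: float | None
    importance: np.ndarray  # per-feature mean |SHAP|
    spread: np.ndarray  # per-feature std of SHAP across samples
    degenerate: bool = False


def decompose_variance(shap_by_sample: np.ndarray) -> UncertaintyDecomposition:
    """Decompose SHAP variability over hypothesis samples.

    Parameters
    ----------
    shap_by_sample : array with shape ``(S, T, ...)`` — hypothesis samples
        on axis 0, within-sample replicates (per-tree SHAP values) on
        axis 1, any trailing shape (feature, or instance x feature x class).
        Single-replicate samples (T = 1) have ``sigma2_s = 0``.

    Raises
    ------
    ValueError
        If fewer than 2 samples are given (epistemic variance undefined).
    """
    x = np.asarray(shap_by_sample, dtype=float)
    if x.ndim < 2:
        raise ValueError("expected shape (samples, replicates, ...)")
    if x.shape[0] < 2:
        raise ValueError("epistemic variance undefined for fewer than 2 samples")
    mu_s = x.mean(axis=1)  # (S, ...)
    sigma2_s = x.var(axis=1)  # population convention
    A = sigma2_s.mean(axis=0)
    E = mu_s.var(axis=0)
    C = (mu_s * sigma2_s).mean(axis=0) - mu_s.mean(axis=0) * sigma2_s.mean(axis=0)
    return UncertaintyDecomposition(
        aleatoric=A, epistemic=E, entanglement=C, total=A + E - C, mu_s=mu_s, sigma2_s=sigma2_s
    )


def entanglement_correlation(
    importance: np.ndarray, spread: np.ndarray
) -> EntanglementCorrelation:
    """Pearson correlation between per-feature importance and instability.

    ``importance`` is the mean absolute SHAP per feature, ``spread`` the
    standard deviation of SHAP across hypothesis samples.  With a
    zero-variance vector the correlation is undefined and a flagged null is
    returned instead.
    """
    imp = np.asarray(importance, dtype=float)
    spr = np.asarray(spread, dtype=float)
    if imp.shape != spr.shape or imp.ndim != 1:
        raise ValueError("importance and spread must be matching 1-d vectors")
    if imp.size < 3:
        raise ValueError("need at least 3 features for a meaningful correlation")
    if np.ptp(imp) == 0 or np.ptp(spr) == 0:
        return EntanglementCorrelation(rho=None, importance=imp, spread=spr, degenerate=True)
    rho = float(stats.pearsonr(imp, spr).statistic)
    return EntanglementCorrelation(rho=rho, importance=imp, spread=spr)
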