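"""End-to-end orchestration: sampling -> SHAP -> decomposition -> reports.

``run_ubiqtree`` executes the full uncertainty-quantification pipeline over
a trained (or freshly trained) bagged forest: per-tree OOB reliability,
softmax weighting, Dirichlet hypothesis sampling, constrained sub-ensemble
SHAP over an explanation instance set, the aleatoric/epistemic/entanglement
decomposition, the uncertainty-aware aggregation, the evidence layer, and
the importance-vs-instability correlation — per class — then writes the
report files, a run manifest, and (optionally) figures.

Two runs with identical manifests produce byte-identical report files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import sklearn
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from . import __version__
from .aggregation import aggregate_uncertainty
from .decomposition import decompose_variance, entanglement_correlation
from .evidence import (
    acquisition_ranking,
    belief,
    build_bpa,
    build_partition,
    conflict,
    plausibility,
    uncertainty_cdf,
)
from .model_adapter import EnsembleView, tree_weights
from .sampling import SamplingConfig, dirichlet_sample
from .shap_core import shap_tensor_for_samples

logger = logging.getLogger("ubiqtree")

__all__ = ["RunConfig", "RunBundle", "run_ubiqtree", "load_table"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    data: str | None = None  # CSV path; alternatively pass X/y to run_ubiqtree
    target: str = "target"
    n_estimators: int = 50
    max_depth: int | None = 6
    class_weight: str | None = "balanced"
    test_size: float = 0.3
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    partition_m: int = 10
    n_explain: int = 200  # stratified explanation subsample of the test split
    background_size: int = 128
    instance: int | None = None  # explain a single test row instead
    out_dir: str | None = None
    make_plots: bool = True
    seed: int = 42


@dataclass
class RunBundle:
    """In-memory result of a run; the file outputs mirror these fields."""

    report: pd.DataFrame
    decomposition: pd.DataFrame
    evidence: dict
    entanglement: dict
    summary: dict
    manifest: dict
    feature_names: list[str]
    class_names: list[str]
    sample_values: np.ndarray  # (S, d, c) per-sample class-level SHAP
    per_tree_values: np.ndarray  # (S, T, d, c) instance-averaged per-slot SHAP
    out_dir: Path | None = None


def load_table(path: str, target: str) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Read a CSV with a named target column; label-encode categoricals.

    Non-numeric columns (and a non-numeric target) are encoded as integer
    codes over their sorted unique values; the mapping is returned so it
    can be written as a sidecar JSON next to the run outputs.
    """
    df = pd.read_csv(path)
    if target not in df.columns:
        raise ValueError(f"target column {target!r} not in {path}")
    encodings: dict[str, dict] = {}
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            levels = sorted(df[col].astype(str).unique())
            mapping = {lv: i for i, lv in enumerate(levels)}
            df[col] = df[col].astype(str).map(mapping)
            encodings[col] = mapping
    y = df[target]
    X = df.drop(columns=[target])
    return X, y, encodings


def run_ubiqtree(
    cfg: RunConfig,
    X: pd.DataFrame | None = None,
    y: pd.Series | None = None,
) -> RunBundle:
    """Run the full pipeline; see module docstring for the stage order.

    Data comes either from ``cfg.data`` (CSV) or the ``X``/``y`` arguments.
    Returns a :class:`RunBundle`; when ``cfg.out_dir`` is set the report
    CSVs, JSON summaries, manifest and figures are written there.
    """
    t0 = time.perf_counter()
    encodings: dict = {}
    if X is None or y is None:
        if cfg.data is None:
            raise ValueError("either cfg.data or X/y must be provided")
        X, y, encodings = load_table(cfg.data, cfg.target)
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y), name=cfg.target)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("target must have at least 2 classes")
    feature_names = [str(c) for c in X.columns]

    # --- train / ingest ----------------------------------------------------
    X_tr, X_te, y_tr, y_te = train_test_split(
        X.to_numpy(dtype=float),
        y.to_numpy(),
        test_size=cfg.test_size,
        stratify=y.to_numpy(),
        random_state=cfg.seed,
    )
    forest = RandomForestClassifier(
        n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth,
        class_weight=cfg.class_weight,
        bootstrap=True,
        random_state=cfg.seed,
    ).fit(X_tr, y_tr)
    if not forest.estimators_:
        raise ValueError("model has no trees")
    ensemble = EnsembleView.from_sklearn(forest, n_train=len(X_tr))
    logger.info("trained forest K=%d in %.2fs", ensemble.n_trees, time.perf_counter() - t0)

    # --- weights and hypothesis samples ------------------------------------
    tw = tree_weights(ensemble, X_tr, y_tr, beta=cfg.sampling.beta)
    for rec in tw.warnings:
        logger.warning(rec)
    samples = dirichlet_sample(tw.softmax, cfg.sampling)

    # --- explanation set and background ------------------------------------
    rng = np.random.default_rng(cfg.seed)
    if cfg.instance is not None:
        X_ex = X_te[[cfg.instance]]
    else:
        X_ex = _stratified_subsample(X_te, y_te, cfg.n_explain, rng)
    bg_idx = rng.choice(len(X_tr), size=min(cfg.background_size, len(X_tr)), replace=False)
    B = X_tr[np.sort(bg_idx)]

    t1 = time.perf_counter()
    tensor, _ = shap_tensor_for_samples(
        samples, ensemble, X_ex, B,
        feature_names=feature_names,
        class_names=[str(c) for c in classes],
    )
    logger.info("SHAP tensor %s in %.2fs", tensor.values.shape, time.perf_counter() - t1)

    # --- statistics ---------------------------------------------------------
    S, T, n, d, c = tensor.values.shape
    dec = decompose_variance(tensor.values)  # components per (n, d, c)
    dec_class = {
        "aleatoric": dec.aleatoric.mean(axis=0),
        "epistemic": dec.epistemic.mean(axis=0),
        "entanglement": dec.entanglement.mean(axis=0),
        "total": dec.total.mean(axis=0),
    }
    mu_s = tensor.values.mean(axis=1)  # (S, n, d, c) sub-ensemble means
    v = mu_s.mean(axis=1)  # (S, d, c) class-level per-sample values
    per_tree_class = tensor.values.mean(axis=2)  # (S, T, d, c)
    importance = np.abs(mu_s).mean(axis=(0, 1))  # (d, c) mean |SHAP|
    spread = v.std(axis=0)  # (d, c) epistemic std across samples

    report_rows, dec_rows, evidence_out, entangle_out = [], [], {}, {}
    for ci, cls in enumerate(classes):
        gammas, variances = [], []
        ev_cls = {}
        for fi, feat in enumerate(feature_names):
            row = aggregate_uncertainty(v[:, fi, ci])
            report_rows.append(
                {
                    "class": str(cls),
                    "feature": feat,
                    "mean_shap": row.mean,
                    "std": row.std,
                    "ci_low": row.ci_low,
                    "ci_high": row.ci_high,
                    "entropy_nats": row.entropy,
                    "sign_stability": row.sign_stability,
                    "stability_category": row.stability_category,
                    "action": row.action,
                }
            )
            dec_rows.append(
                {
                    "class": str(cls),
                    "feature": feat,
                    "aleatoric": dec_class["aleatoric"][fi, ci],
                    "epistemic": dec_class["epistemic"][fi, ci],
                    "entanglement": dec_class["entanglement"][fi, ci],
                    "total": dec_class["total"][fi, ci],
                }
            )
            sources = [per_tree_class[s, :, fi, ci] for s in range(S)]
            part = build_partition(np.concatenate(sources), cfg.partition_m)
            bpa = build_bpa(sources, part)
            gdist = uncertainty_cdf(v[:, fi, ci])
            gammas.append(gdist.entropy)
            variances.append(float(v[:, fi, ci].var()))
            ev_cls[feat] = {
                "cell_edges": part.edges.tolist(),
                "degenerate": part.degenerate,
                "bel_singletons": [belief(bpa, {j}) for j in range(part.n_cells)],
                "pl_singletons": [plausibility(bpa, {j}) for j in range(part.n_cells)],
                "conflict": conflict(bpa, part),
                "gamma_entropy": gdist.entropy if np.isfinite(gdist.entropy) else None,
            }
        ranking = acquisition_ranking(variances, np.nan_to_num(gammas, neginf=-1e18), feature_names)
        for rank, feat in enumerate(ranking):
            ev_cls[feat]["acquisition_rank"] = rank
        evidence_out[str(cls)] = ev_cls
        corr = entanglement_correlation(importance[:, ci], spread[:, ci])
        entangle_out[str(cls)] = {
            "rho": corr.rho,
            "importance": corr.importance.tolist(),
            "spread": corr.spread.tolist(),
            "degenerate": corr.degenerate,
        }

    report = pd.DataFrame(report_rows)
    dec_df = pd.DataFrame(dec_rows)
    summary = {
        "mean_shap": v.mean(axis=0),
        "std_dev": spread,
        "ci_95": np.percentile(v, [2.5, 97.5], axis=0),
        "aleatoric": dec_class["aleatoric"],
        "epistemic": dec_class["epistemic"],
        "entanglement": dec_class["entanglement"],
        "entropy": report.pivot(index="feature", columns="class", values="entropy_nats")
        .loc[feature_names]
        .to_numpy(),
        "sign_stability": report.pivot(index="feature", columns="class", values="sign_stability")
        .loc[feature_names]
        .to_numpy(),
    }

    manifest = {
        "ubiqtree_version": __version__,
        "config": _manifest_config(cfg),
        "n_train": int(len(X_tr)),
        "n_test": int(len(X_te)),
        "n_explained": int(X_ex.shape[0]),
        "background_rows": int(B.shape[0]),
        "classes": [str(cc) for cc in classes],
        "feature_names": feature_names,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }

    bundle = RunBundle(
        report=report,
        decomposition=dec_df,
        evidence=evidence_out,
        entanglement=entangle_out,
        summary=summary,
        manifest=manifest,
        feature_names=feature_names,
        class_names=[str(cc) for cc in classes],
        sample_values=v,
        per_tree_values=per_tree_class,
    )

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.csv", index=False)
        dec_df.to_csv(out / "decomposition.csv", index=False)
        _dump_json(out / "evidence.json", evidence_out)
        _dump_json(out / "entanglement.json", entangle_out)
        _dump_json(out / "manifest.json", manifest)
        if encodings:
            _dump_json(out / "encodings.json", encodings)
        bundle.out_dir = out
        if cfg.make_plots:
            from .plotting import render_reports

            render_reports(bundle, out)
    logger.info("pipeline done in %.2fs", time.perf_counter() - t0)
    return bundle


def _stratified_subsample(X_te, y_te, n_explain, rng) -> np.ndarray:
    if n_explain >= len(X_te):
        return X_te
    idx = []
    classes, counts = np.unique(y_te, return_counts=True)
    # proportional allocation, at least one row per class
    alloc = np.maximum(1, np.round(n_explain * counts / counts.sum()).astype(int))
    while alloc.sum() > n_explain:
        alloc[np.argmax(alloc)] -= 1
    for cls, k in zip(classes, alloc):
        rows = np.flatnonzero(y_te == cls)
        idx.append(rng.choice(rows, size=min(k, len(rows)), replace=False))
    idx = np.sort(np.concatenate(idx))
    return X_te[idx]


def _manifest_config(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["sampling"] = asdict(cfg.sampling)
    # where the outputs land does not determine what is computed
    d.pop("out_dir")
    d.pop("make_plots")
    return d


def _dump_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, allow_nan=True)
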