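"""Figures: uncertainty-banded SHAP summaries, per-feature KDE grids, and
importance-vs-instability scatters."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import gaussian_kde

__all__ = ["render_reports"]

TOP_SUMMARY = 15
TOP_KDE = 4


def render_reports(bundle, out_dir, top_kde: int = TOP_KDE) -> list[Path]:
    """Write three figure families per class; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for ci, cls in enumerate(bundle.class_names):
        v = bundle.sample_values[:, :, ci]  # (S, d)
        ent = bundle.entanglement[cls]
        imp = np.asarray(ent["importance"])
        order = np.argsort(imp)[::-1]
        paths.append(_summary_fig(bundle, v, imp, order, cls, out))
        paths.append(_kde_fig(bundle, v, order[: min(top_kde, len(order))], cls, out))
        paths.append(_scatter_fig(ent, cls, out))
    return paths


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name)


def _summary_fig(bundle, v, imp, order, cls, out: Path) -> Path:
    top = order[: min(TOP_SUMMARY, len(order))]
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(top) + 1.5))
    ypos = np.arange(len(top))[::-1]
    for yp, fi in zip(ypos, top):
        vals = v[:, fi]
        mu, sd = vals.mean(), vals.std()
        ax.barh(yp, mu, xerr=2 * sd, color="#4878cf", alpha=0.7, height=0.6,
                error_kw={"ecolor": "#2b4b8f", "capsize": 3})
        ax.plot(vals, np.full_like(vals, yp) + np.linspace(-0.18, 0.18, len(vals)),
                ".", ms=2.5, color="gray", alpha=0.6)
    ax.axvline(0.0, color="k", ls="--", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels([bundle.feature_names[fi] for fi in top])
    ax.set_xlabel("SHAP value (mean ± 2σ across hypothesis samples)")
    ax.set_title(f"class {cls}: top features by mean |SHAP|")
    fig.tight_layout()
    p = out / f"summary_{_slug(cls)}.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p


def _kde_fig(bundle, v, top, cls, out: Path) -> Path:
    n = len(top)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 2.8), squeeze=False)
    for ax, fi in zip(axes[0], top):
        vals = v[:, fi]
        lo, hi = np.percentile(vals, [2.5, 97.5])
        if np.ptp(vals) == 0:
            ax.axvline(vals[0], color="#c44e52", ls="-", lw=2)
            ax.text(0.5, 0.5, "degenerate\n(point mass)", ha="center", va="center",
                    transform=ax.transAxes)
        else:
            kde = gaussian_kde(vals)
            grid = np.linspace(vals.min(), vals.max(), 256)
            dens = kde(grid)
            ax.plot(grid, dens, color="#4878cf")
            band = (grid >= lo) & (grid <= hi)
            ax.fill_between(grid[band], dens[band], alpha=0.3, color="#4878cf",
                            label="95% credible")
            ax.axvline(vals.mean(), color="#c44e52", ls="--", label="mean")
        ax.set_title(bundle.feature_names[fi], fontsize=9)
        ax.set_xlabel("SHAP")
    axes[0][0].set_ylabel("density")
    fig.suptitle(f"class {cls}: SHAP distributions across hypothesis samples", fontsize=10)
    fig.tight_layout()
    p = out / f"kde_{_slug(cls)}.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p


def _scatter_fig(ent, cls, out: Path) -> Path:
    imp = np.asarray(ent["importance"])
    spr = np.asarray(ent["spread"])
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    ax.plot(imp, spr, "o", ms=5, color="#4878cf", alpha=0.8)
    rho = ent.get("rho")
    label = "ρ undefined" if rho is None else f"ρ = {rho:.2f}"
    ax.annotate(label, xy=(0.05, 0.92), xycoords="axes fraction", fontsize=11)
    ax.set_xlabel("mean |SHAP| (importance)")
    ax.set_ylabel("std of SHAP across samples")
    ax.set_title(f"class {cls}: importance vs. instability")
    fig.tight_layout()
    p = out / f"scatter_{_slug(cls)}.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p
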