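"""Optional figures for comparison reports (matplotlib, file output only)."""

from __future__ import annotations

import numpy as np

from .analysis import GenomeComparison, PCAResult


def _agg_backend():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_fnorm_distribution(comparison: GenomeComparison, path) -> None:
    plt = _agg_backend()
    fn = [c.normalized.f_norm for c in comparison.conditions]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(fn, bins=min(20, max(5, len(fn))), color="steelblue", edgecolor="k")
    ax.axvline(0.5, color="firebrick", ls="--", lw=1)
    ax.set_xlabel(r"$F_\mathrm{norm}$")
    ax.set_ylabel("conditions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ts_tv(comparison: GenomeComparison, path) -> None:
    plt = _agg_backend()
    data = [
        [c.ts_tv_empirical for c in comparison.conditions],
        [c.ts_tv_min for c in comparison.conditions],
        [c.ts_tv_max for c in comparison.conditions],
    ]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.boxplot(data, tick_labels=["empirical", "minimizing", "maximizing"])
    ax.set_ylabel("transitions / transversions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca_scatter(result: PCAResult, path) -> None:
    plt = _agg_backend()
    colors = {"empirical": "k", "minimizing": "tab:blue", "maximizing": "tab:red"}
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = np.array(result.groups)
    for grp in dict.fromkeys(result.groups):
        sel = groups == grp
        ax.scatter(result.scores[sel, 0],
                   result.scores[sel, 1] if result.scores.shape[1] > 1
                   else np.zeros(sel.sum()),
                   s=18, label=grp, color=colors.get(grp, "gray"), alpha=0.8)
    ax.set_xlabel(f"PC1 ({100 * result.explained_variance_ratio[0]:.0f}%)")
    if result.scores.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({100 * result.explained_variance_ratio[1]:.0f}%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
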