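"""Figure helpers: PCA score plots, importance bars, predicted-vs-actual."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stats_ml import GroupPCA, ModelReport


def plot_pca_scores(results: dict[str, GroupPCA], path: str | Path) -> Path:
    """One score panel per size group, colored by growth phase."""
    path = Path(path)
    fig, axes = plt.subplots(1, len(results), figsize=(4 * len(results), 3.5), squeeze=False)
    for ax, (group, res) in zip(axes[0], sorted(results.items())):
        for phase in res.index["phase"].unique():
            mask = (res.index["phase"] == phase).to_numpy()
            ax.scatter(res.scores[mask, 0], res.scores[mask, 1], s=8, label=phase, alpha=0.6)
        evr = res.explained_variance_ratio
        ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
        ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
        ax.set_title(group)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_model_report(report: ModelReport | dict, path: str | Path) -> Path:
    """Importance bars next to the predicted-vs-actual scatter."""
    path = Path(path)
    rep = report.to_dict() if isinstance(report, ModelReport) else report
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    names = list(rep["importances"])
    ax1.bar(names, [rep["importances"][n] for n in names])
    ax1.set_ylabel("importance")
    ax1.tick_params(axis="x", rotation=45)
    actual = [p[0] for p in rep["predictions"]]
    pred = [p[1] for p in rep["predictions"]]
    ax2.scatter(actual, pred)
    lims = [min(actual + pred), max(actual + pred)]
    ax2.plot(lims, lims, "k--", lw=0.8)
    ax2.set_xlabel("actual ARA")
    ax2.set_ylabel("predicted ARA")
    ax2.set_title(f"{rep['size_group']}: test R$^2$ = {rep['test_r2']:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
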