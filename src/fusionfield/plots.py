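"""Report figures: accuracy distributions, norm.dev violins, importance."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def accuracy_boxplots(summaries: dict, path: str | Path) -> Path:
    """Box plots of R2_val and rRMSEP over splits, per variant x response."""
    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    labels, r2_data, rr_data = [], [], []
    for (variant, response), s in summaries.items():
        labels.append(f"{variant}\n{response}")
        r2_data.append([sp.r2_val for sp in s.splits])
        rr_data.append([sp.rrmsep for sp in s.splits])
    axes[0].boxplot(r2_data, tick_labels=labels)
    axes[0].set_ylabel(r"$R^2_{val}$")
    axes[1].boxplot(rr_data, tick_labels=labels)
    axes[1].set_ylabel("rRMSEP [%]")
    for ax in axes:
        ax.tick_params(axis="x", labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def normdev_violins(preds: pd.DataFrame, path: str | Path) -> Path:
    """Violin plots of norm.dev per mixture and year."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    groups, labels = [], []
    for (mix, year), grp in preds.groupby(["mixture", "year"]):
        vals = grp["norm_dev"].dropna().to_numpy()
        if vals.size:
            groups.append(vals)
            labels.append(f"{mix}\nY{year}")
    ax.violinplot(groups, showmedians=True)
    ax.set_xticks(np.arange(1, len(labels) + 1), labels)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_ylabel("norm.dev  $(\\hat{y}-y)/(\\hat{y}+y)$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def importance_boxplot(summary, path: str | Path, top: int = 10) -> Path:
    """Per-split importance distributions of the top median-ranked variables."""
    imp = pd.DataFrame([s.importance for s in summary.splits])
    order = imp.median().sort_values(ascending=False).index[:top]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.boxplot([imp[c] for c in order], orientation="horizontal",
               tick_labels=[str(c) for c in order])
    ax.invert_yaxis()
    ax.set_xlabel("permutation importance (increase in OOB MSE)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
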