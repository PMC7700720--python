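"""Optional matplotlib figures for survival outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .survival import RocCurve, kaplan_meier


def plot_km_by_group(durations, events, groups, path) -> None:
    """Step-style Kaplan-Meier curves, one line per group."""
    curves = kaplan_meier(durations, events, groups)
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, (sf, median) in sorted(curves.items()):
        ax.step(sf.index, sf["survival"], where="post", label=f"{label} (median {median:.0f}d)")
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(roc: RocCurve, path) -> None:
    """Time-dependent ROC curve at the fitted horizon."""
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.plot(roc.fpr, roc.tpr, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.3f} at {roc.horizon:.0f} days")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
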