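"""Repeatability and agreement scatter plots (Bland-Altman style)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .reliability import AgreementSummary

__all__ = ["repeatability_plot", "agreement_plot"]


def repeatability_plot(scores_a, scores_b, path: str | Path, label_a="first reading", label_b="second reading"):
    """Scatter of one reading against the other with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(a, b, s=25, edgecolor="k", facecolor="none")
    lim = (min(a.min(), b.min()) - 1, max(a.max(), b.max()) + 1)
    ax.plot(lim, lim, lw=1, color="gray")
    ax.set_xlim(lim), ax.set_ylim(lim)
    ax.set_xlabel(label_a)
    ax.set_ylabel(label_b)
    ax.set_title("Repeatability")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def agreement_plot(summary: AgreementSummary, path: str | Path, title="Agreement (95 % limits of agreement)"):
    """Bland-Altman plot: differences against means with bias and limits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(summary.means, summary.diffs, s=25, edgecolor="k", facecolor="none")
    ax.axhline(summary.bias, color="tab:blue", lw=1.2, label=f"bias {summary.bias:.2f}")
    for lim, name in zip(summary.loa95, ("lower", "upper")):
        ax.axhline(lim, color="tab:red", lw=1, ls="--", label=f"{name} LoA {lim:.2f}")
    ax.set_xlabel("mean of paired scores")
    ax.set_ylabel("difference of paired scores")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
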