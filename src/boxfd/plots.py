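"""Optional matplotlib figures: per-subject ln-ln fit and cohort ROC curve."""
from __future__ import annotations

from pathlib import Path

import numpy as np


def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_lnln_fit(curve, fd_result, path, title: str = "") -> None:
    """ln(count) vs ln(caliber) with the fitted line; FD = |slope|."""
    plt = _mpl()
    x = np.log(curve.calibers_mm)
    y = np.log(curve.counts)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(x, y, "o", color="#3b7dd8")
    xs = np.array([x.min(), x.max()])
    ax.plot(xs, fd_result.slope * xs + fd_result.intercept, "-", color="#c0392b",
            label=f"FD = {fd_result.fd:.4f}  (R² = {fd_result.r_squared:.3f})")
    ax.set_xlabel("ln caliber (mm)")
    ax.set_ylabel("ln occupied boxes")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(scores, labels, roc_result, path) -> None:
    """Empirical ROC polyline with the AUC and Youden point annotated."""
    plt = _mpl()
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=int)
    thresholds = np.r_[np.inf, np.sort(np.unique(s))[::-1]]
    tpr = [(s[lab == 1] >= t).mean() for t in thresholds]
    fpr = [(s[lab == 0] >= t).mean() for t in thresholds]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, "-", color="#3b7dd8",
            label=f"AUC = {roc_result.auc:.3f} "
                  f"[{roc_result.ci_low:.3f}, {roc_result.ci_high:.3f}]")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.plot(1 - roc_result.specificity, roc_result.sensitivity, "o",
            color="#c0392b", label=f"Youden cutoff = {roc_result.cutoff:.4f}")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(frameon=False, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
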