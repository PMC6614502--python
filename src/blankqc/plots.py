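"""Diagnostic figures: PCA scores along run order, conditioning curves,
cluster profiles.  All functions take/return matplotlib objects so they
compose with user figures; ``save_all`` writes the standard PNG set."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import pca_overview


def plot_scores_run_order(results, ax=None):
    """PC1/PC2 of the informative samples against run order, blanks marked."""
    table = results.corrected.subset_features(results.informative_ids)
    seq = table.sequence
    keep = seq.index[seq["sample_class"].isin(["sample", "QC"])]
    X = table.area[keep].to_numpy(dtype=float).T
    scores, _, frac = pca_overview(X, n_components=2)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for c, (pc, f) in enumerate(zip(scores.T, frac)):
        ax.plot(keep, pc, marker=".", lw=0.8, label=f"PC{c + 1} ({100 * f:.1f}%)")
    blanks = seq.index[seq["sample_class"] == "blank"]
    for b in blanks:
        ax.axvline(b, color="red", alpha=0.25, lw=0.8)
    ax.set_xlabel("run order (red: blanks)")
    ax.set_ylabel("score")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_conditioning_curve(curve, ax=None, title=None):
    """Delta (line, left axis) and significant-feature counts (right axis)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    n = curve["position_n"]
    ax.plot(n, curve["delta"], "o-", color="k", label="delta")
    sig = curve["p_value"] < 0.05
    ax.plot(n[sig], curve["delta"][sig] + 0.03, "k*", ms=8)
    ax.set_ylim(0, 1.1)
    ax.set_xlabel("conditioning samples n")
    ax.set_ylabel("delta")
    ax2 = ax.twinx()
    for metric, color in (("area", "C0"), ("rt", "C1"), ("width", "C2")):
        col = f"n_sig_{metric}"
        if col in curve:
            ax2.plot(n, curve[col], "s--", color=color, alpha=0.7, label=metric)
    ax2.set_ylabel("# significant features")
    ax2.legend(loc="upper right", fontsize=8)
    if title:
        ax.set_title(title)
    return ax


def plot_cluster_profiles(results, ax=None):
    """Median normalised intensity profile per cluster."""
    if results.median_profiles is None:
        raise ValueError("no clustering in results")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    prof = results.median_profiles
    x = np.arange(prof.shape[1])
    for lab, row in prof.iterrows():
        ax.plot(x, row.to_numpy(), "o-", label=f"cluster {lab}")
    ax.set_xticks(x, prof.columns, rotation=45, fontsize=7)
    ax.set_ylabel("median z-scored area")
    ax.legend(fontsize=8)
    return ax


def save_all(results, out_dir) -> list:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _save(name, fn, *a, **kw):
        try:
            ax = fn(*a, **kw)
        except ValueError:
            return
        fig = ax.get_figure()
        fig.tight_layout()
        p = out / name
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    _save("scores_run_order.png", plot_scores_run_order, results)
    for ctype, curve in results.curves.items():
        _save(f"curve_{ctype}.png", plot_conditioning_curve, curve,
              title=f"{ctype} deconditioning")
    if results.median_profiles is not None:
        _save("cluster_profiles.png", plot_cluster_profiles, results)
    return written
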