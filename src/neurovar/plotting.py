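"""Figure helpers: every figure has a TSV twin produced by the caller."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .robustness import PowerMap
from .stats import AssociationTrack
from .dominance import DominanceTrack

__all__ = ["plot_association", "plot_dominance", "plot_power_map"]


def plot_association(assoc: AssociationTrack, ax=None, title: str = ""):
    """r track with gray FDR-significance bars and a Bayes-factor color bar."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(assoc.times, assoc.r, color="tab:blue", lw=1.2, label=f"{assoc.kind} r")
    sig = np.where(assoc.q_sig, assoc.r, np.nan)
    ax.bar(assoc.times, sig, width=np.median(np.diff(assoc.times)), color="0.6",
           label="FDR significant")
    if assoc.bf is not None:
        ymin = min(np.nanmin(assoc.r), 0) - 0.08
        ax.scatter(
            assoc.times, np.full_like(assoc.times, ymin),
            c=np.log10(assoc.bf), cmap="coolwarm", s=2, marker="s",
        )
    ax.axvline(0, color="k", lw=0.6)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("r")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=7)
    return ax


def plot_dominance(dom: DominanceTrack, ax=None, title: str = ""):
    """Stacked total-dominance contributions over time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.stackplot(
        dom.times, dom.td_var, dom.td_amp,
        labels=["ΔSD", "ΔAmplitude"], colors=["tab:purple", "tab:orange"],
    )
    ax.plot(dom.times, dom.r2_full, "k-", lw=0.8, label="$R^2$ full")
    ax.axvline(0, color="k", lw=0.6)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("$R^2$")
    ax.set_title(title)
    ax.legend(fontsize=7)
    return ax


def plot_power_map(pmap: PowerMap, ax=None, title: str = ""):
    """Probability-of-significance heat map with the 80% contour."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    im = ax.pcolormesh(pmap.times, pmap.sizes, pmap.prob, vmin=0, vmax=1,
                       cmap="viridis", shading="nearest")
    if pmap.prob.max() >= 0.8 and pmap.sizes.size > 1:
        ax.contour(pmap.times, pmap.sizes, pmap.prob, levels=[0.8],
                   colors="w", linewidths=1.0)
    plt.colorbar(im, ax=ax, label="P(significant)")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(f"n {pmap.axis}")
    ax.set_title(title)
    return ax
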