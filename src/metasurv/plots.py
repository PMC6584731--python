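"""Basic Kaplan-Meier and forest plots for survival meta-analyses."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .meta import MetaEstimate
from .survstats import KMCurve


def plot_km(curves: dict[str, KMCurve], ax=None, title: str = ""):
    """Step plot of one KM curve per labelled group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.step(curve.times, curve.survival, where="post", label=label)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax


def plot_forest(metas: Sequence[MetaEstimate], ax=None, title: str = ""):
    """Forest plot of pooled hazard ratios with 95% intervals."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.4 * len(metas) + 1.5))
    ys = np.arange(len(metas))[::-1]
    for y, m in zip(ys, metas):
        lo, hi = m.ci95
        ax.plot([np.exp(lo), np.exp(hi)], [y, y], color="k", lw=1)
        ax.plot([m.hr], [y], "ks", ms=4)
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels([m.gene for m in metas])
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (pooled)")
    if title:
        ax.set_title(title)
    return ax
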