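"""Optional matplotlib views of the agreement analysis (scatter, Bland–Altman, CSF)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .csf import CsfParams, csf_value
from .report import bland_altman

__all__ = ["correlation_plot", "bland_altman_plot", "csf_plot"]


def correlation_plot(x, y, labels=("method A", "method B"), ax=None):
    """Paired log CS scatter with the identity line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=12, alpha=0.6)
    lo = min(np.min(x), np.min(y))
    hi = max(np.max(x), np.max(y))
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
    ax.set_xlabel(f"log CS ({labels[0]})")
    ax.set_ylabel(f"log CS ({labels[1]})")
    return ax


def bland_altman_plot(x, y, labels=("method A", "method B"), ax=None):
    """Difference-vs-mean plot with bias and 95% limits of agreement."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ba = bland_altman(x, y)
    ax.scatter((x + y) / 2.0, x - y, s=12, alpha=0.6)
    for v, style in ((ba["bias"], "-"), (ba["loa_lower"], "--"), (ba["loa_upper"], "--")):
        ax.axhline(v, color="k", ls=style, lw=0.8)
    ax.set_xlabel(f"mean log CS ({labels[0]}, {labels[1]})")
    ax.set_ylabel(f"difference ({labels[0]} − {labels[1]})")
    return ax


def csf_plot(points, params: CsfParams | None = None, ax=None):
    """log CS vs spatial frequency with an optional fitted log-parabola."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    pts = np.asarray(list(points), float)
    ax.scatter(pts[:, 0], pts[:, 1], s=18)
    if params is not None:
        sf = np.geomspace(pts[:, 0].min() / 1.3, pts[:, 0].max() * 1.3, 200)
        ax.plot(sf, csf_value(sf, params), lw=1.2)
    ax.set_xscale("log")
    ax.set_xlabel("spatial frequency (cpd)")
    ax.set_ylabel("log10 CS")
    return ax
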