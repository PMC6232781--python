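"""Matplotlib figures for the streaming and topography results."""

from __future__ import annotations

import numpy as np

from .erp import TopographyMap
from .streaming import OnsetLockedAverage

_COLORS = {"none": "tab:red", "left": "tab:green", "right": "tab:blue"}


def plot_onset_locked(avg: OnsetLockedAverage, title: str = "", ax=None):
    """Mean class probabilities vs time before onset, sd as shaded band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 4))
    for i, name in enumerate(("none", "left", "right")):
        ax.plot(avg.times, avg.mean[:, i], color=_COLORS[name], label=name)
        ax.fill_between(
            avg.times,
            avg.mean[:, i] - avg.sd[:, i],
            avg.mean[:, i] + avg.sd[:, i],
            color=_COLORS[name],
            alpha=0.2,
            linewidth=0,
        )
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("time relative to rotation onset (s)")
    ax.set_ylabel("probability")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(loc="center left")
    ax.set_title(title or f"onset-locked probabilities (n={avg.n_events})")
    return ax


def plot_topography(topo: TopographyMap, title: str = "", ax=None):
    """Per-electrode values as a labeled bar map (no montage geometry needed)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(8, 3.5))
    x = np.arange(len(topo.channels))
    ax.bar(x, topo.values, color=np.where(topo.values >= 0, "tab:blue", "tab:orange"))
    ax.set_xticks(x)
    ax.set_xticklabels(topo.channels, rotation=90, fontsize=7)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("mean pre-onset voltage (recorded units)")
    ax.set_title(title or topo.provenance)
    return ax
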