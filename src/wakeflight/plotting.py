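"""Simple diagnostic plots for the pipeline's main objects."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_relative_density", "plot_per_bird_hr_effects"]


def plot_relative_density(offsets, coplanar_band: float = 0.75, ax=None):
    """2-D density of follower offsets behind the leader (top view).

    ``offsets`` is an (n, 3) array of (dx, dy, dz) in the leader's
    frame; only near-co-planar samples are shown.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    offsets = np.asarray(offsets, dtype=float)
    sel = np.abs(offsets[:, 2]) <= coplanar_band
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.hexbin(offsets[sel, 1], offsets[sel, 0], gridsize=40, mincnt=1, cmap="viridis")
    ax.plot(0, 0, "w^", markersize=10, markeredgecolor="k")
    ax.set_xlabel("right of leader (m)")
    ax.set_ylabel("ahead of leader (m)")
    ax.set_title("co-planar follower positions")
    ax.set_aspect("equal")
    return ax


def plot_per_bird_hr_effects(per_bird, ax=None):
    """Forest-style plot of per-bird in-wake heart-rate changes.

    ``per_bird`` is the table from
    :meth:`wakeflight.models.HeartRateResults.bootstrap_per_bird`
    (columns ``pct_difference``, ``pct_lower``, ``pct_upper``).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    y = np.arange(len(per_bird))
    est = per_bird["pct_difference"].to_numpy(float)
    if {"pct_lower", "pct_upper"} <= set(per_bird.columns):
        lo = per_bird["pct_lower"].to_numpy(float)
        hi = per_bird["pct_upper"].to_numpy(float)
        ax.errorbar(est, y, xerr=[est - lo, hi - est], fmt="o", color="k", capsize=3)
    else:
        ax.plot(est, y, "ko")
    ax.axvline(0.0, color="grey", linestyle="--", linewidth=1)
    ax.set_yticks(y, [str(b) for b in per_bird.index])
    ax.set_ylabel("bird")
    ax.set_xlabel("heart-rate change in-wake (%)")
    return ax
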