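"""Convenience plots for rate curves and model fits (matplotlib)."""

from __future__ import annotations

import numpy as np

from .measure import RateSeries


def plot_rate_series(series: RateSeries, ax=None, label=None, color=None):
    """Mean rate vs the series axis with a shaded 95% CI band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = series.axis_values
    m = series.mean_rate_um_per_s
    ci = series.ci95_halfwidth
    line, = ax.plot(x, m, label=label, color=color)
    ax.fill_between(x, m - ci, m + ci, alpha=0.3, color=line.get_color())
    ax.set_xlabel(series.axis.replace("_", " "))
    ax.set_ylabel("extension rate (µm/s)")
    if label:
        ax.legend()
    return ax


def plot_growth_fit(results, cell, trajectories=(), ax=None):
    """Observed lengths (thin) with the fitted mean growth curve (thick)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t_max = 0.0
    for traj in trajectories:
        ax.plot(traj.times_s, traj.lengths_um, color="gray", alpha=0.3, lw=0.8)
        t_max = max(t_max, traj.times_s[-1])
    t = np.linspace(0.0, t_max or 120.0, 200)
    ax.plot(t, results.predict(cell, t), color="C1", lw=2, label="fitted mean")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cable length (µm)")
    ax.legend()
    return ax
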