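"""Optional diagnostic figures.  Plotting never affects numerics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_activation_map",
    "plot_slowness_trajectory",
    "plot_dfa",
    "plot_epoch_average",
]


def plot_activation_map(beat, layout, slowness=None, ax=None):
    """Colour-coded activation times on the electrode layout, optionally
    with the propagation direction derived from the slowness vector."""
    ax = ax or plt.gca()
    xs, ys, ts = [], [], []
    for row in layout.itertuples(index=False):
        if row.electrode in beat.activation_times:
            xs.append(row.x_cm)
            ys.append(row.y_cm)
            ts.append((beat.activation_times[row.electrode] - beat.mean_time) * 1000)
    sc = ax.scatter(xs, ys, c=ts, s=120, cmap="viridis")
    plt.colorbar(sc, ax=ax, label="activation time - mean (ms)")
    if slowness is not None and slowness.norm > 0:
        d = slowness.vec / slowness.norm * 0.15
        ax.annotate("", xy=(d[0], d[1]), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", lw=2))
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_aspect("equal")
    return ax


def plot_slowness_trajectory(vectors, ax=None):
    """Tips of successive slowness vectors in the s_x-s_y plane."""
    ax = ax or plt.gca()
    tips = np.array([v.vec for v in vectors if v is not None])
    ax.plot(tips[:, 0], tips[:, 1], "-", color="0.7", lw=0.5)
    ax.plot(tips[:, 0], tips[:, 1], "r.", ms=3)
    ax.set_xlabel("$s_x$ (s/cm)")
    ax.set_ylabel("$s_y$ (s/cm)")
    ax.set_aspect("equal")
    return ax


def plot_dfa(result, ax=None):
    """log-log fluctuation plot with the fitted slope."""
    ax = ax or plt.gca()
    ax.loglog(result.n_values, result.df_values, "o")
    fit = np.exp(result.alpha * np.log(result.n_values)
                 + np.log(result.df_values[0]) - result.alpha * np.log(result.n_values[0]))
    ax.loglog(result.n_values, fit, "-", label=rf"$\alpha$ = {result.alpha:.2f}")
    ax.set_xlabel("segment length n")
    ax.set_ylabel("DF(n)")
    ax.legend()
    return ax


def plot_epoch_average(epoch, ax=None):
    """Per-repeat and mean normalised beat rate around an intervention."""
    ax = ax or plt.gca()
    for row in epoch.rows:
        ax.plot(epoch.time_axis, row, color="0.7", lw=0.7)
    ax.plot(epoch.time_axis, epoch.mean_trace, color="C0", lw=2, label="mean")
    ax.axvline(0.0, color="k", ls=":")
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set_xlabel("time from motor start (s)")
    ax.set_ylabel("normalised beat rate")
    ax.legend()
    return ax
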