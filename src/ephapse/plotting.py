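"""Thin optional plotting helpers (requires matplotlib).

Produces the space-space heatmap view of a run: v(lateral, z) at a few
snapshot times, colored by membrane potential.
"""

from __future__ import annotations

import numpy as np


def plot_snapshots(result, times=None, ax_list=None, cmap="viridis",
                   vmin=None, vmax=None):
    """Heatmaps of v(lateral, axial) at the requested snapshot times.

    Returns the matplotlib figure.  ``times`` defaults to five equally
    spaced instants over the run.
    """
    import matplotlib.pyplot as plt

    if times is None:
        times = np.linspace(result.times[0], result.times[-1], 5)
    idx = [int(np.argmin(np.abs(result.times - t))) for t in times]
    if ax_list is None:
        fig, ax_list = plt.subplots(len(idx), 1, sharex=True,
                                    figsize=(8, 1.8 * len(idx)))
        ax_list = np.atleast_1d(ax_list)
    else:
        fig = ax_list[0].figure
    vmin = result.v.min() if vmin is None else vmin
    vmax = result.v.max() if vmax is None else vmax
    extent = [0.0, result.grid.z_extent, result.grid.n_lateral + 0.5, 0.5]
    for ax, i in zip(ax_list, idx):
        im = ax.imshow(result.v[i], aspect="auto", cmap=cmap, vmin=vmin,
                       vmax=vmax, extent=extent)
        ax.set_ylabel(f"t = {result.times[i]:g}")
    ax_list[-1].set_xlabel("z")
    fig.colorbar(im, ax=list(ax_list), label="v")
    return fig


def plot_misi(table, ax=None):
    """Station-averaged mean interspike interval along the fiber."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(table.per_station["z_station"], table.per_station["misi"],
            marker="o")
    ax.set_xlabel("z station")
    ax.set_ylabel("mISI")
    return ax.figure
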