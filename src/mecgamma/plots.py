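"""Figure helpers: spike rasters, clamp-current traces and scalograms."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_raster", "plot_scalogram", "plot_trace"]


def _axes(ax):
    if ax is None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_raster(result, ax=None, max_cells_per_pop=50):
    """Spike raster, I cells (bottom, blue) and E cells (top, red)."""
    ax = _axes(ax)
    n_i = result.network.n_i
    for pop, color, off in (("I", "tab:blue", 0), ("E", "tab:red", n_i)):
        t, g = result.population_spikes(pop)
        keep = g < off + max_cells_per_pop
        ax.plot(t[keep], g[keep], "|", color=color, markersize=2)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("cell id")
    return ax


def plot_trace(result, readout=0, ax=None):
    """Clamp current of one E-population readout."""
    ax = _axes(ax)
    ax.plot(result.t_ms, result.clamp_e_pa[readout], lw=0.5, color="tab:red")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("clamp current (pA)")
    return ax


def plot_scalogram(cs, ax=None):
    """Cycle-averaged scalogram (time within theta cycle x frequency)."""
    ax = _axes(ax)
    m = ax.pcolormesh(cs.cycle_time_ms, cs.freqs_hz, cs.average,
                      shading="auto", cmap="magma")
    ax.set_yscale("log")
    ax.set_xlabel("time in theta cycle (ms)")
    ax.set_ylabel("frequency (Hz)")
    ax.figure.colorbar(m, ax=ax, label="power (pA$^2$)")
    return ax
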