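"""Minimal plotting helpers for threshold maps and traces."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_threshold_map", "plot_trace"]


def plot_threshold_map(tmap, ax=None, **imshow_kw):
    """Threshold map as an image over the scan grid (nan = not excitable)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs, ys = tmap.grid.xs, tmap.grid.ys
    img = tmap.threshold.reshape(len(xs), len(ys)).T
    im = ax.imshow(img, origin="lower",
                   extent=(xs[0], xs[-1], ys[0], ys[-1]),
                   aspect="equal", **imshow_kw)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    plt.colorbar(im, ax=ax, label="threshold (uA)")
    return ax


def plot_trace(trace, ax=None, sites=None):
    """Recorded Vm time series, one line per site."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for k, site in enumerate(trace.sites):
        if sites is not None and site not in sites:
            continue
        ax.plot(trace.t, trace.vm[k], label=f"comp {site}")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("Vm (mV)")
    ax.legend(frameon=False)
    return ax
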