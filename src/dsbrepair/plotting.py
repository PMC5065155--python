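"""Minimal plotting helpers (cosmetics deliberately plain)."""

from __future__ import annotations

import numpy as np

from .model import CHANNELS

_COLORS = {"fast": "tab:red", "slow": "tab:blue", "aej": "tab:green"}


def plot_bands(bands, spec=None, ax=None):
    """Median fit with 0.5 and 0.95 credible envelopes; observed points if
    the spec carries them.  Returns the axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = bands["time_hr"]
    ax.fill_between(t, bands["q025"], bands["q975"], alpha=0.2, label="0.95 CR")
    ax.fill_between(t, bands["q25"], bands["q75"], alpha=0.35, label="0.5 CR")
    ax.plot(t, bands["q50"], "k-", label="median")
    if spec is not None and spec.observed is not None:
        ax.plot(spec.timepoints, spec.observed, "ro", ms=4, label="observed")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("remaining DSBs (dose equivalent, Gy)")
    ax.legend()
    return ax


def plot_occupancy(t, shares, ax=None):
    """Per-channel share of in-process breaks over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i, ch in enumerate(CHANNELS):
        ax.plot(t, 100 * np.asarray(shares)[:, i], color=_COLORS[ch], label=ch)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("share of bound DSBs (%)")
    ax.legend()
    return ax


def plot_activity_timeline(timeline, channel="aej", ax=None):
    """Activity raster: draws sorted by recruitment rate, red where the
    channel holds more than the threshold share of bound breaks."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    i = CHANNELS.index(channel)
    order = np.argsort(timeline["rates"][:, i])
    ax.imshow(
        timeline["active"][order, i, :],
        aspect="auto", cmap="Reds", interpolation="nearest",
        extent=[timeline["time_hr"][0], timeline["time_hr"][-1], 0, len(order)],
    )
    ax.set_xlabel("time (h)")
    ax.set_ylabel(f"posterior draws (sorted by K_{channel})")
    return ax
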