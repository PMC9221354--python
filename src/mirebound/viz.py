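"""Debug plotting utilities (not a scientific deliverable).

A minimal top-down scalp scatter for eyeballing ERD/ERS topographies.
"""

from __future__ import annotations

import numpy as np

from .containers import ERDSTrace

# approximate 2D head positions (x: left-, y: front+) for common 10-20 names
_POS = {
    "Fp1": (-0.3, 0.9), "Fp2": (0.3, 0.9), "F7": (-0.7, 0.55), "F3": (-0.4, 0.55),
    "Fz": (0.0, 0.55), "F4": (0.4, 0.55), "F8": (0.7, 0.55), "FC5": (-0.6, 0.28),
    "FC1": (-0.22, 0.28), "FC2": (0.22, 0.28), "FC6": (0.6, 0.28), "T7": (-0.85, 0.0),
    "C3": (-0.45, 0.0), "Cz": (0.0, 0.0), "C4": (0.45, 0.0), "T8": (0.85, 0.0),
    "CP5": (-0.6, -0.28), "CP1": (-0.22, -0.28), "CP2": (0.22, -0.28),
    "CP6": (0.6, -0.28), "P7": (-0.7, -0.55), "P3": (-0.4, -0.55), "Pz": (0.0, -0.55),
    "P4": (0.4, -0.55), "P8": (0.7, -0.55), "O1": (-0.3, -0.9), "Oz": (0.0, -0.9),
    "O2": (0.3, -0.9),
}


def plot_topomap_debug(trace: ERDSTrace, at_time: float, ax=None):
    """Scatter the per-channel ERD/ERS values at one time point."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    i = int(np.argmin(np.abs(trace.time_axis - at_time)))
    vals = trace.values[:, i]
    lim = max(1.0, np.max(np.abs(vals)))
    for ch, v in zip(trace.channel_labels, vals):
        x, y = _POS.get(ch, (0.0, 0.0))
        ax.scatter(x, y, c=[v], cmap="RdBu_r", vmin=-lim, vmax=lim, s=600)
        ax.annotate(ch, (x, y), ha="center", va="center", fontsize=7)
    circle = __import__("matplotlib.patches", fromlist=["Circle"]).Circle(
        (0, 0), 1.0, fill=False
    )
    ax.add_patch(circle)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"ERD/ERS at {trace.time_axis[i]:.3f} s (%)")
    return ax
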