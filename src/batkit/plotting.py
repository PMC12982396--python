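"""Display helpers. The arcsinh transform exists only here: gating itself
operates on linear intensities."""

from __future__ import annotations

import numpy as np


def arcsinh_transform(values, cofactor: float = 150.0):
    """Standard cytometry display transform: arcsinh(x / cofactor)."""
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


def gate_scatter(events, x: str, y: str, mask=None, ax=None,
                 cofactor: float = 150.0):
    """Scatter plot of two channels with an optional gate mask overlay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xv = arcsinh_transform(events[x], cofactor)
    yv = arcsinh_transform(events[y], cofactor)
    ax.scatter(xv, yv, s=1, alpha=0.3, color="grey", label="all")
    if mask is not None:
        ax.scatter(xv[mask], yv[mask], s=1, alpha=0.5, color="crimson",
                   label="gated")
        ax.legend(markerscale=10)
    ax.set_xlabel(f"arcsinh {x}")
    ax.set_ylabel(f"arcsinh {y}")
    return ax
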