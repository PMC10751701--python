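"""Minimal plotting helpers for transmission/attenuation curves."""

from __future__ import annotations

import numpy as np


def plot_curves(curves, labels=None, ax=None, percent=False, ylabel=None):
    """Plot one or more angular curves against gantry angle.

    ``curves`` is a sequence of TransmissionCurve/AttenuationCurve.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    labels = labels or [getattr(c, "role", None) and c.role.value or f"curve {i}"
                        for i, c in enumerate(curves)]
    scale = 100.0 if percent else 1.0
    for curve, label in zip(curves, labels):
        order = np.argsort(curve.angles)
        ax.plot(curve.angles[order], scale * curve.values[order],
                marker=".", ms=3, lw=1, label=str(label))
        unc = getattr(curve, "uncertainty", None)
        if unc is not None:
            ax.fill_between(curve.angles[order],
                            scale * (curve.values - unc)[order],
                            scale * (curve.values + unc)[order], alpha=0.25)
    ax.set_xlabel("gantry angle (deg)")
    ax.set_ylabel(ylabel or ("value (%)" if percent else "value (fraction)"))
    ax.legend(fontsize=8)
    return ax
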