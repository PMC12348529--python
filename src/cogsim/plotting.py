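"""Quick-look plots for curves produced by the scenarios."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_stress_strain", "plot_force_displacement"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_stress_strain(curves, ax=None):
    """Plot one or several StressStrainCurve objects (strain vs MPa)."""
    ax = _axes(ax)
    for curve in np.atleast_1d(curves):
        ax.plot(curve.strain, curve.stress, label=curve.label or None)
    ax.set_xlabel("engineering strain")
    ax.set_ylabel("nominal stress (MPa)")
    if any(getattr(c, "label", "") for c in np.atleast_1d(curves)):
        ax.legend()
    return ax


def plot_force_displacement(curves, ax=None):
    """Plot one or several ForceDisplacementCurve objects (mm vs N)."""
    ax = _axes(ax)
    for curve in np.atleast_1d(curves):
        style = "--" if getattr(curve, "truncated", False) else "-"
        ax.plot(curve.displacement, curve.force, style, label=curve.label or None)
    ax.set_xlabel("displacement (mm)")
    ax.set_ylabel("reaction force (N)")
    if any(getattr(c, "label", "") for c in np.atleast_1d(curves)):
        ax.legend()
    return ax
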