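"""Optional figure helpers (phase-distance scatter with the fitted line)."""

from __future__ import annotations

import numpy as np

from .precession import PrecessionMeasures


def plot_phase_distance(d, phases_deg, measures: PrecessionMeasures = None, ax=None, repeat=True):
    """Phase-versus-normalized-distance scatter, phases repeated over two
    cycles for readability, with the fitted regression line if given.

    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    d = np.asarray(d, dtype=float)
    ph = np.mod(np.asarray(phases_deg, dtype=float), 360.0)
    ax.scatter(d, ph, s=8, c="k")
    if repeat:
        ax.scatter(d, ph + 360.0, s=8, c="k")
    if measures is not None:
        xs = np.linspace(0, 1, 100)
        ys = measures.phi0 + measures.slope * xs
        for shift in (0.0, 360.0, -360.0, 720.0):
            ax.plot(xs, ys + shift, c="g", lw=1.2)
        sig = "p={:.3g}".format(measures.pvalue)
        ax.set_title(f"slope={measures.slope:.1f} deg, {sig}", fontsize=9)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 720 if repeat else 360)
    ax.set_xlabel("normalized distance")
    ax.set_ylabel("theta phase (deg)")
    return ax
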