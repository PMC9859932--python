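"""Planet plots: polar views of d* comparisons around a centered cell class."""

from __future__ import annotations

import numpy as np

from .classes import ComparisonResult

__all__ = ["plot_planet"]


def plot_planet(result: ComparisonResult, ax=None, path=None):
    """Draw a planet plot: the centered class sits at the origin and every
    compared class orbits on a circle whose radius is its d* value.

    Returns the matplotlib Axes; if *path* is given the figure is saved
    there (format from the extension, e.g. ``.svg`` or ``.png``).
    """
    import matplotlib
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure(figsize=(6, 6))
        ax = fig.add_subplot(111, projection="polar")
    else:
        fig = ax.figure

    ax.set_ylim(0, 1.05)
    ax.set_yticks([0.25, 0.5, 0.75, 1.0])
    ax.set_xticks([])
    for value, keys in result.rings:
        theta_ring = np.linspace(0, 2 * np.pi, 200)
        ax.plot(theta_ring, np.full_like(theta_ring, value),
                lw=0.6, color="0.8", zorder=1)
        angles = np.linspace(0, 2 * np.pi, len(keys), endpoint=False) + 0.25
        for angle, key in zip(angles, keys):
            ax.plot([angle], [value], "o", ms=9, zorder=3)
            ax.annotate("/".join(key), (angle, value),
                        textcoords="offset points", xytext=(6, 6), fontsize=8)
    ax.plot([0], [0], "*", ms=16, color="goldenrod", zorder=4)
    ax.set_title(f"{result.mode}: {'/'.join(result.center)}", fontsize=10)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
    return ax
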