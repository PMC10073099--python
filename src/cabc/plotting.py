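"""ABC-curve plotting."""

from __future__ import annotations

import numpy as np

from .core import ABCPartition, ABCCurve


def render_abc_plot(curve: ABCCurve, part: ABCPartition | None = None,
                    ax=None, path=None, title: str | None = None):
    """Plot an ABC curve with its reference curves and computed boundaries.

    Shows the interpolated ABC curve (blue), the identity distribution
    (the diagonal, magenta) and the uniform-distribution reference curve
    ``-p**2 + 2p`` (grey dashed); if a partition is given, red vertical
    lines mark the A|B (Juran) and B|C (break-even) boundaries.
    Returns the matplotlib axes; saves to ``path`` if given.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    p = np.linspace(0, 1, 512)
    ax.plot(p, curve(p), color="tab:blue", lw=2, label="ABC curve")
    ax.plot(p, p, color="magenta", lw=1, label="identity ($x_i$ = const)")
    ax.plot(p, -p**2 + 2 * p, color="grey", ls="--", lw=1, label="uniform")
    if part is not None:
        ax.axvline(part.juran[0], color="red", lw=1)
        ax.axvline(part.break_even[0], color="red", lw=1)
        ax.plot(*part.juran, "ro", ms=5)
        ax.plot(*part.break_even, "ro", ms=5)
        ax.text(part.juran[0], 0.02, " A|B", color="red")
        ax.text(part.break_even[0], 0.02, " B|C", color="red")
    ax.set_xlabel("effort (fraction of items)")
    ax.set_ylabel("yield (fraction of total value)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
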