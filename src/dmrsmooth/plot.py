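"""Basic inspection plot: difference curve, calls, and derivative track."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_region_tracks(result, xlim=None, path=None):
    """Three stacked panels for one ChromosomeResult.

    Raw and smoothed difference curve with DMR spans, then the estimated
    first-derivative track with its pointwise confidence band. Returns the
    figure; saves to ``path`` if given.
    """
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(10, 6))
    pos = result.curve.pos
    ax1.plot(pos, result.curve.d, ".", ms=1.5, color="0.7", label="per-site d")
    ax1.plot(pos, result.smoothed, color="C0", lw=1.2, label="smoothed")
    for c in result.calls:
        if c.significant:
            ax1.axvspan(c.start, c.end, color="C3", alpha=0.25)
    ax1.axhline(0, color="k", lw=0.5)
    ax1.set_ylabel("methylation difference")
    ax1.legend(loc="upper right", fontsize=8)

    tr = result.track
    ax2.plot(tr.pos, tr.alpha1, color="C1", lw=1.0)
    ax2.fill_between(tr.pos, tr.ci_l, tr.ci_u, color="C1", alpha=0.25, lw=0)
    ax2.axhline(0, color="k", lw=0.5)
    ax2.set_ylabel("estimated derivative")
    ax2.set_xlabel(f"{result.chrom} position (bp)")
    if xlim:
        ax1.set_xlim(*xlim)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
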