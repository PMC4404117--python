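"""Optional plotting: raw data + fitted spline, and per-window W values.

Import is deferred to call time so the package works without matplotlib.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .windows import MarkerSeries, WindowSet, fit_smoothing_spline


def plot_analysis(
    series: MarkerSeries,
    window_set: WindowSet,
    path: Path,
    threshold: float | None = None,
) -> None:
    """Two-panel figure: raw values with the fitted spline and window
    boundaries (top), W per window with an optional threshold line (bottom)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = fit_smoothing_spline(series)
    grid = np.linspace(*fit.domain, 2000)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    ax1.plot(series.positions, series.values, ".", ms=3, color="gray", label="raw")
    ax1.plot(grid, fit(grid), color="red", lw=1.5, label="spline")
    for b in window_set.boundaries:
        ax1.axvline(b, color="k", ls="--", lw=0.6)
    ax1.set_ylabel("value")
    ax1.legend(loc="best", fontsize=8)
    for w in window_set:
        ax2.hlines(w.w_stat, w.start, w.stop, color="C0", lw=2)
    if threshold is not None:
        ax2.axhline(threshold, color="red", lw=1)
    ax2.set_xlabel(f"position on {series.chrom} (bp)")
    ax2.set_ylabel("W")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
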