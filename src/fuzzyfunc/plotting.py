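"""Heatmap rendering for reduced-precision sweep results."""

from __future__ import annotations

import numpy as np

from .experiments import SweepResult

__all__ = ["sweep_heatmap"]


def sweep_heatmap(sweep: SweepResult, metric: str = "aupr", namespace: str | None = None,
                  ax=None):
    """Render one sweep as a heatmap of relative metric differences.

    Crashed cells are marked with a red X.  ``namespace`` defaults to the
    first namespace root in the result.
    """
    import matplotlib.pyplot as plt

    if namespace is None:
        namespace = sorted(sweep.reference_metrics)[0]
    fds = list(dict.fromkeys(c.fmt_double for c in sweep.cells))
    fss = list(dict.fromkeys(c.fmt_single for c in sweep.cells))
    grid = np.full((len(fds), len(fss)), np.nan)
    crashes = []
    for c in sweep.cells:
        i, j = fds.index(c.fmt_double), fss.index(c.fmt_single)
        if c.crashed:
            crashes.append((i, j))
        else:
            grid[i, j] = c.diffs[namespace][metric]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(fss) + 2, 1.0 * len(fds) + 1.5))
    vmax = np.nanmax(np.abs(grid)) or 1e-12
    im = ax.imshow(grid, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    for i, j in crashes:
        ax.plot(j, i, marker="x", color="red", markersize=14, markeredgewidth=3)
    for i in range(len(fds)):
        for j in range(len(fss)):
            if np.isfinite(grid[i, j]):
                ax.text(j, i, f"{100 * grid[i, j]:+.1f}%", ha="center", va="center",
                        fontsize=8)
    ax.set_xticks(range(len(fss)), fss, rotation=45)
    ax.set_yticks(range(len(fds)), fds)
    ax.set_xlabel("single-precision class format")
    ax.set_ylabel("double-precision class format")
    ax.set_title(f"{metric} relative difference vs IEEE ({sweep.mode}, {namespace})")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
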