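"""Basic diagnostic plots: training curves and phase-diagram heat maps."""

from __future__ import annotations

import numpy as np

from .training import TrainingTrace


def plot_training_curve(trace: TrainingTrace, path) -> None:
    """Training error per cycle (one line per target), saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for i in range(trace.errors.shape[1]):
        ax.plot(np.arange(1, trace.n_cycles + 1), trace.errors[:, i],
                label=f"target {i}")
    ax.set_xlabel("drive cycle")
    ax.set_ylabel("training error")
    ax.set_yscale("log")
    if trace.errors.shape[1] > 1:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_phase_diagram(points, path, value: str = "label") -> None:
    """Heat map of sweep outcomes over the two swept parameters.

    ``points`` is the list of PhasePoint from `sweep_phase_diagram`; with
    ``value="label"`` cells show the modal phase label per grid point,
    otherwise the mean of the named diagnostic.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(points[0].coords)
    xs = sorted({p.coords[names[0]] for p in points})
    ys = sorted({p.coords[names[1]] for p in points})
    labels = sorted({p.label for p in points})
    grid = np.full((len(ys), len(xs)), np.nan)
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            cell = [p for p in points
                    if p.coords[names[0]] == x and p.coords[names[1]] == y]
            if not cell:
                continue
            if value == "label":
                counts = {lab: sum(p.label == lab for p in cell) for lab in labels}
                grid[i, j] = labels.index(max(counts, key=counts.get))
            else:
                grid[i, j] = float(np.mean([p.diagnostics[value] for p in cell]))
    fig, ax = plt.subplots(figsize=(4.6, 3.6))
    im = ax.imshow(grid, origin="lower", aspect="auto",
                   extent=(-0.5, len(xs) - 0.5, -0.5, len(ys) - 0.5))
    ax.set_xticks(range(len(xs)), [f"{x:g}" for x in xs])
    ax.set_yticks(range(len(ys)), [f"{y:g}" for y in ys])
    ax.set_xlabel(names[0])
    ax.set_ylabel(names[1])
    if value == "label":
        cbar = fig.colorbar(im, ticks=range(len(labels)))
        cbar.ax.set_yticklabels(labels)
    else:
        fig.colorbar(im, label=value)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
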