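"""Quick-look figures for traces, sweeps and lattice snapshots."""

from __future__ import annotations

import numpy as np


def plot_trace(trace, ax=None):
    """Furrow depth (and acceptance rate) against Monte Carlo time."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    f = trace.frame
    ax.plot(f["mcs"], f["depth"], lw=1.5, color="tab:blue")
    ax.set_xlabel("MCS")
    ax.set_ylabel("furrow depth (h0)", color="tab:blue")
    ax2 = ax.twinx()
    ax2.plot(f["mcs"], f["acceptance"], lw=0.8, color="tab:orange", alpha=0.6)
    ax2.set_ylabel("acceptance rate", color="tab:orange")
    ax.set_title(f"{trace.schedule_id} (seed {trace.seed})")
    return ax


def plot_sweep(result, ax=None):
    """Mean final depth over a two-axis stiffness grid as a heat map."""
    import matplotlib.pyplot as plt
    names = list(result.axes)
    if len(names) != 2:
        raise ValueError("heat map needs exactly two grid axes")
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    xs, ys = result.axes[names[0]], result.axes[names[1]]
    grid = np.full((len(ys), len(xs)), np.nan)
    for _, row in result.summary.iterrows():
        i = ys.index(row[names[1]])
        j = xs.index(row[names[0]])
        grid[i, j] = row["mean_depth"]
    im = ax.imshow(grid, origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(xs)), [f"{v:g}" for v in xs])
    ax.set_yticks(range(len(ys)), [f"{v:g}" for v in ys])
    ax.set_xlabel(names[0])
    ax.set_ylabel(names[1])
    ax.figure.colorbar(im, ax=ax, label="mean final depth (h0)")
    return ax


def plot_state(state, ax=None, by="kind"):
    """Label map of a simulation state, coloured by kind or parent cell."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    if by == "kind":
        img = state.kind[state.lattice]
        cmap = "tab10"
    elif by == "cell":
        img = np.mod(state.parent[state.lattice] * 7.13, 17.0)
        cmap = "tab20"
    else:
        raise ValueError("by must be 'kind' or 'cell'")
    ax.imshow(img, interpolation="nearest", cmap=cmap)
    ax.set_axis_off()
    return ax
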