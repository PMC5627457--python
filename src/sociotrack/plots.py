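"""Publication-style summary figures.

Two plots cover the assay's standard visual checks: the group-mean
binned investigation curve with SEM ribbons for each stimulus, and the
transition raster (one row of dots per subject with the binned group
mean overlaid).
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def plot_binned_investigation(pooled: dict, bin_width_s: float, path,
                              labels=("stimulus 1", "stimulus 2")) -> None:
    """Group mean +/- SEM investigation time per 20-s bin, per stimulus."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    n_bins = len(pooled["binned_mean_stim1"])
    t = (np.arange(n_bins) + 0.5) * bin_width_s
    for key, label, color in (("stim1", labels[0], "tab:red"),
                              ("stim2", labels[1], "tab:blue")):
        mean = pooled[f"binned_mean_{key}"]
        sem = pooled[f"binned_sem_{key}"]
        ax.plot(t, mean, color=color, label=label)
        ax.fill_between(t, mean - sem, mean + sem, color=color, alpha=0.25,
                        linewidth=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"investigation (s / {bin_width_s:.0f}-s bin)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_transition_raster(transition_times: list[np.ndarray],
                           session_length_s: float, bin_width_s: float,
                           path) -> None:
    """One row of transition dots per subject, with the per-bin group
    mean overlaid."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    for row, times in enumerate(transition_times):
        times = np.asarray(times, dtype=float)
        ax.plot(times, np.full_like(times, row + 1), ".",
                color="tab:blue", markersize=3)
    edges = np.arange(0, session_length_s + bin_width_s, bin_width_s)
    counts = np.stack([np.histogram(np.asarray(t, dtype=float),
                                    bins=edges)[0]
                       for t in transition_times])
    mean = counts.mean(axis=0)
    ax2 = ax.twinx()
    ax2.plot((edges[:-1] + edges[1:]) / 2, mean, color="tab:red")
    ax2.set_ylabel("mean transitions / bin", color="tab:red")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("subject")
    ax.set_xlim(0, session_length_s)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
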