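"""Figures: decoded tracks and stationary-probability curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

STATE_COLOURS = ["#e6b422", "#5b3e90", "#2e8b57"]  # foraging, inactive, extra


def plot_decoded_track(series, decode, path) -> None:
    """Track coloured by Viterbi state."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for n in np.unique(decode.states):
        sel = decode.states == n
        ax.scatter(series.x[sel], series.y[sel], s=8,
                   color=STATE_COLOURS[(n - 1) % len(STATE_COLOURS)], label=f"state {n}")
    ax.plot(series.x, series.y, lw=0.4, color="grey", zorder=0)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    ax.legend(frameon=False)
    ax.set_title(series.track_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_stationary_curve(curve, grid, xlabel, path) -> None:
    """Per-state stationary probabilities with CI ribbons if present."""
    fig, ax = plt.subplots(figsize=(6, 4))
    n_states = sum(c.startswith("p_state") for c in curve.columns)
    for n in range(1, n_states + 1):
        c = STATE_COLOURS[(n - 1) % len(STATE_COLOURS)]
        ax.plot(grid, curve[f"p_state{n}"], color=c, label=f"state {n}")
        if f"lo_state{n}" in curve.columns:
            ax.fill_between(grid, curve[f"lo_state{n}"], curve[f"hi_state{n}"],
                            color=c, alpha=0.2, lw=0)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("stationary probability")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
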