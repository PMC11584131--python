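"""Two-panel trajectory plots: sample replicates beside the replicate mean."""

from __future__ import annotations

import pathlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .alleles import ALLELE_ORDER
from .population import Trajectory, mean_trajectory

__all__ = ["plot_trajectories"]

_COLORS = {
    "W": "#666666",
    "G": "#2ca02c",
    "U": "#1f77b4",
    "R": "#d62728",
    "V": "#9467bd",
    "S": "#ff7f0e",
}


def build_figure(trajectories: list[Trajectory], n_show: int = 5, seed: int = 0):
    """Two-panel figure: sampled replicates (left) and their mean (right).

    The left panel overlays ``n_show`` randomly selected replicates
    (all of them when fewer are available); the right panel shows the
    pointwise mean of every replicate.  One line per allele class.
    """
    if not trajectories:
        raise ValueError("at least one trajectory is required")
    rng = np.random.default_rng(seed)
    k = min(n_show, len(trajectories))
    chosen = rng.choice(len(trajectories), size=k, replace=False)
    mean = mean_trajectory(trajectories)

    fig, (ax_l, ax_r) = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    gens = np.arange(mean.allele_freq.shape[0])
    for idx in chosen:
        for i, state in enumerate(ALLELE_ORDER):
            ax_l.plot(
                gens,
                trajectories[idx].allele_freq[:, i],
                color=_COLORS[state.name],
                alpha=0.5,
                lw=0.8,
            )
    for i, state in enumerate(ALLELE_ORDER):
        ax_r.plot(
            gens,
            mean.allele_freq[:, i],
            color=_COLORS[state.name],
            lw=1.8,
            label=state.name.lower(),
        )
    ax_l.set_title(f"{k} replicate(s)")
    ax_r.set_title(f"mean of {len(trajectories)} replicates")
    for ax in (ax_l, ax_r):
        ax.set_xlabel("generation")
        ax.set_ylim(-0.02, 1.02)
    ax_l.set_ylabel("X-allele frequency")
    ax_r.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_trajectories(
    trajectories: list[Trajectory],
    out_path,
    n_show: int = 5,
    seed: int = 0,
    dpi: int = 150,
) -> pathlib.Path:
    """Render the two-panel trajectory figure to an image file."""
    fig = build_figure(trajectories, n_show=n_show, seed=seed)
    out_path = pathlib.Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)
    return out_path
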