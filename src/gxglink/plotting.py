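"""Two-panel scenario figures: allele frequencies left, components right.

Plotting is isolated here so headless pipelines never touch the graphics
stack unless asked.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from gxglink.coevolution_simulator import TrajectoryRecord

__all__ = ["plot_scenario"]


def plot_scenario(
    trajectory: TrajectoryRecord,
    components: pd.DataFrame,
    path: str | Path | None = None,
):
    """Frequency trajectories (left) and variance-component time series (right)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax_freq, ax_comp) = plt.subplots(1, 2, figsize=(10, 3.5), constrained_layout=True)
    gens = range(trajectory.host_freqs.shape[0])
    for k in range(trajectory.host_freqs.shape[1]):
        ax_freq.plot(gens, trajectory.host_freqs[:, k], label=f"host {k}")
        ax_freq.plot(gens, trajectory.parasite_freqs[:, k], ls="--", alpha=0.6,
                     label=f"parasite {k}")
    ax_freq.set(xlabel="generation", ylabel="genotype frequency", ylim=(0, 1))
    ax_freq.legend(fontsize=6, ncol=2)

    for comp, label in (
        ("sigma2_host", "host"),
        ("sigma2_parasite", "parasite"),
        ("sigma2_gxg", "host × parasite"),
        ("sigma2_error", "error"),
    ):
        ax_comp.plot(components["generation"], components[comp], label=label)
    ax_comp.set(xlabel="generation", ylabel="variance component")
    ax_comp.legend(fontsize=7)

    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
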