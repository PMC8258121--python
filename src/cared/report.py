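"""Reporting: degeneration-progress curves and the modulus table."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .experiments import GROUPS, IterationHistory  # noqa: E402

__all__ = ["plot_history", "modulus_table"]

_TITLES = {
    "reorientation_deg": "Fibril reorientation [deg]",
    "collagen_rel": "Relative collagen density",
    "fcd_rel": "Relative FCD",
    "fluid_frac": "Fluid volume fraction",
}


def plot_history(history: IterationHistory, path) -> None:
    """Per-layer progression curves of the four degeneration readouts."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, (metric, title) in zip(axes.ravel(), _TITLES.items()):
        for layer in GROUPS:
            y = history.series(layer, metric)
            ax.plot(range(len(y)), y, label=layer)
        ax.set_title(title)
        ax.set_xlabel("iteration")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def modulus_table(records: list[dict], path=None) -> pd.DataFrame:
    """Equilibrium-modulus table (scenario, before, after, % change).

    Each record needs keys ``scenario``, ``modulus_initial`` and
    ``modulus_final`` [MPa]; the percent change is derived.
    """
    df = pd.DataFrame(records)
    df["change_pct"] = 100.0 * (df.modulus_final - df.modulus_initial) \
        / df.modulus_initial
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)
    return df
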