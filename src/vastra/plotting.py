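"""Morphometry plots: diameter / length / branching ratio versus order."""

from __future__ import annotations

import pandas as pd


def plot_order_stats(order_table: pd.DataFrame, reference: pd.DataFrame | None = None, path=None):
    """Log-scale diameter, length and daughter/parent ratios per order.

    Optionally overlays a reference morphometry table (same column
    conventions).  Returns the matplotlib figure; saves to ``path`` when
    given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, col, err in (
        (axes[0], "diameter_mm", "diameter_mm_se"),
        (axes[1], "length_mm", "length_mm_se"),
    ):
        ax.errorbar(
            order_table["order"], order_table[col], yerr=order_table[err],
            marker="o", label="simulated",
        )
        if reference is not None and col in reference.columns:
            ax.plot(reference["order"], reference[col], "s--", label="reference")
        ax.set_yscale("log")
        ax.set_xlabel("Strahler order")
        ax.set_ylabel(col.replace("_", " "))
        ax.legend(fontsize=8)
    ax = axes[2]
    for col, mk in (("Ds_over_Dp", "o"), ("Dl_over_Dp", "^")):
        ax.plot(order_table["order"], order_table[col], mk + "-", label=col)
        if reference is not None and col in reference.columns:
            ax.plot(reference["order"], reference[col], mk + "--", alpha=0.5)
    ax.set_xlabel("Strahler order")
    ax.set_ylabel("daughter / parent diameter")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
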