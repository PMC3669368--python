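"""Minimal plotting helpers (optional; requires matplotlib)."""

from __future__ import annotations

import pandas as pd


def plot_power_vs_parameter(power_table: pd.DataFrame, parameter: str, ax=None,
                            out=None):
    """Line plot of mean power against one design parameter, one line per
    method; returns the matplotlib Axes."""
    import matplotlib

    if out is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for method, rows in power_table.groupby("method"):
        mean = rows.groupby(parameter)["power"].mean()
        ax.plot(mean.index, mean.values, marker="o", label=method)
    ax.set_xlabel(parameter)
    ax.set_ylabel("estimated power")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
    return ax
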