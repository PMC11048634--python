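"""Plotting helpers (matplotlib is imported lazily so the core stays light)."""

from __future__ import annotations

from .trials import PosteriorTable, TrialResult


def plot_posterior_table(table: PosteriorTable, ax=None):
    """Horizontal tornado-style bar chart of a one-way sensitivity table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * max(len(table), 4) + 1))
    frame = table.frame.iloc[::-1]
    ax.barh(frame["scenario"], 100 * frame["posterior"], color="#4878a8")
    node, state = table.target
    ax.set_xlabel(f"P({node} = {state})  [%]")
    ax.set_title("One-way sensitivity")
    return ax


def plot_arm_comparison(result: TrialResult, ax=None):
    """Grouped bars of per-arm ODB and healthy likelihood."""
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    names = list(result.arms)
    odb = [result.arms[n].odb.odb for n in names]
    healthy = [result.arms[n].odb.healthy_pct / 100 for n in names]
    x = np.arange(len(names))
    ax.bar(x - 0.2, odb, width=0.4, label="ODB")
    ax.bar(x + 0.2, healthy, width=0.4, label="healthy likelihood (fraction)")
    ax.set_xticks(x, names, rotation=15, ha="right")
    ax.legend()
    ax.set_title(result.trial.name)
    return ax
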