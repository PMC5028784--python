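"""Simple figures for the two headline outputs.

Matplotlib is an optional dependency (``pip install actipain[plot]``);
these helpers import it lazily.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_endurance_bins", "plot_importance"]

_BIN_LABELS = ("0", "1-24", "25-49", "50-74", ">=75")


def plot_endurance_bins(summaries: pd.DataFrame, ax=None):
    """Grouped box plot of minutes spent in each endurance bin by group.

    ``summaries`` is the activity-summary table with ``endurance_*`` columns
    and a ``group`` column.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    cols = ["endurance_zero", "endurance_1_24", "endurance_25_49",
            "endurance_50_74", "endurance_75_plus"]
    groups = sorted(summaries.group.unique())
    width = 0.35
    for gi, g in enumerate(groups):
        sub = summaries[summaries.group == g]
        pos = np.arange(len(cols)) + (gi - 0.5) * width
        ax.boxplot(
            [sub[c] for c in cols], positions=pos, widths=width * 0.9,
            tick_labels=[""] * len(cols),
        )
    ax.set_xticks(np.arange(len(cols)))
    ax.set_xticklabels(_BIN_LABELS)
    ax.set_xlabel("% of individual maximum activity")
    ax.set_ylabel("minutes per week")
    ax.set_title("Endurance profile by group " + " / ".join(groups))
    return ax


def plot_importance(result, ax=None):
    """Dot plot of per-run forest importances with the threshold lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(result.variables) + 1.5))
    ypos = np.arange(len(result.variables))
    for label, imp in result.importances.items():
        ax.plot(imp, ypos, "o", label=label, alpha=0.7)
    thr = max(result.thresholds.values())
    ax.axvline(thr, linestyle="--", color="k", linewidth=1)
    ax.axvline(0, color="0.7", linewidth=0.5)
    ax.set_yticks(ypos)
    ax.set_yticklabels(result.variables)
    ax.set_xlabel("OOB permutation importance (increase in MSE)")
    ax.legend(fontsize=7)
    return ax
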