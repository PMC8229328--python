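"""A plain plotting helper for per-state speed summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .constants import PERCENTILE_KEYS
from .stats import summaries_frame


def plot_state_percentiles(summaries, path=None, ax=None):
    """Box-style overview of home gait-speed percentiles by medication state."""
    df = summaries_frame(summaries)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    colors = {"ON": "tab:green", "not_ON": "tab:orange"}
    for state, grp in df.groupby("state"):
        med = grp[list(PERCENTILE_KEYS)].median()
        ax.plot(range(len(PERCENTILE_KEYS)), med, marker="o",
                color=colors.get(state, "gray"), label=state)
    ax.set_xticks(range(len(PERCENTILE_KEYS)), PERCENTILE_KEYS)
    ax.set_ylabel("gait speed (m/s)")
    ax.set_xlabel("home speed percentile")
    ax.legend(title="state")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
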