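"""Diagnostic plots: a minimal superplot of hierarchical replicate data."""

from __future__ import annotations

import numpy as np

from kymotility.stats import SuperplotSummary

__all__ = ["superplot"]


def superplot(summaries: dict[str, SuperplotSummary], ylabel: str = "", ax=None):
    """Draw a superplot: per-unit values as small dots, group means as large
    dots, a box spanning the quartiles with the median marked, and whiskers
    at the 10th/90th percentiles.  One column per condition."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(summaries) + 1.5, 3.5))
    rng = np.random.default_rng(0)  # fixed jitter, purely cosmetic
    for i, (name, s) in enumerate(summaries.items()):
        xs = i + rng.uniform(-0.18, 0.18, s.n_values)
        ax.plot(xs, s.values, "o", ms=2.5, alpha=0.4, color="gray", zorder=1)
        ax.plot(
            i + np.linspace(-0.1, 0.1, s.n_groups),
            s.group_means,
            "o",
            ms=8,
            zorder=3,
        )
        ax.add_patch(
            plt.Rectangle(
                (i - 0.25, s.quartile1), 0.5, s.quartile3 - s.quartile1,
                fill=False, edgecolor="k", zorder=2,
            )
        )
        ax.hlines(s.pooled_median, i - 0.25, i + 0.25, color="orange", zorder=2)
        ax.vlines(i, s.p10, s.quartile1, color="k", zorder=2)
        ax.vlines(i, s.quartile3, s.p90, color="k", zorder=2)
    ax.set_xticks(range(len(summaries)), list(summaries))
    ax.set_ylabel(ylabel)
    return ax
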