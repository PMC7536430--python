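"""Optional rendering of evaluation results (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .evaluation import CaseReport

__all__ = ["plot_case_reports", "plot_group_proportions"]


def plot_case_reports(reports: list[CaseReport], threshold: int = 7, ax=None):
    """Box-style per-case view: achievable-MC distribution summary with the
    per-rater selected counts overlaid and the grading threshold marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(reports) * 0.6), 4))
    for i, r in enumerate(reports):
        ax.vlines(i, r.dist_min, r.dist_max, color="0.7", lw=1)
        ax.vlines(i, r.dist_q25, r.dist_q75, color="0.4", lw=5)
        ax.plot(i, r.dist_median, "_", color="k", ms=12)
        for _, group, mc, *_ in r.raters:
            ax.plot(i, mc, "x", ms=5, alpha=0.8)
    ax.axhline(threshold, color="r", ls=":", lw=1)
    ax.set_xticks(range(len(reports)), [r.slide_id for r in reports], rotation=90)
    ax.set_ylabel("mitotic count / 10 HPF")
    return ax


def plot_group_proportions(summaries: dict, ax=None):
    """Forest-style plot of per-group upper-half / upper-quarter proportions
    with their 95% Wilson intervals."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.6 * len(summaries) + 1))
    y = 0
    labels = []
    for group, s in summaries.items():
        for key, marker in (("top_half", "o"), ("top_quarter", "s")):
            lo, hi = s[f"ci_{key}"]
            ax.plot([lo, hi], [y, y], color="0.5", lw=2)
            ax.plot(s[f"prop_{key}"], y, marker, color="k")
            labels.append(f"{group} {key.replace('_', ' ')}")
            y += 1
    ax.set_yticks(np.arange(y), labels)
    ax.set_xlim(-0.02, 1.02)
    ax.set_xlabel("proportion of selections")
    return ax
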