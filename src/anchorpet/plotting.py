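"""Optional matplotlib rendering of vote profiles (requires the `plot` extra)."""

from __future__ import annotations

from typing import Optional

from .breakpoints import BreakpointPrediction, VoteProfile


def plot_profile(
    profile: VoteProfile,
    prediction: Optional[BreakpointPrediction] = None,
    ax=None,
):
    """Vote totals along the locus, with the called interval shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    ax.fill_between(
        range(1, profile.votes.size + 1), profile.votes, step="mid", alpha=0.8
    )
    ax.set_xlabel(f"{profile.locus} position (bp)")
    ax.set_ylabel("votes")
    if prediction is not None and prediction.interval is not None:
        ax.axvspan(*prediction.interval, color="tab:red", alpha=0.3,
                   label=f"{prediction.status.value} ({prediction.format_interval()})")
        ax.legend(loc="upper right", frameon=False)
    return ax
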