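"""Convenience figures: weekly reporting rate, incidence vs sentinel series."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_weekly_reporting_rate(weekly, calendar, path) -> None:
    """Weekly reporting rate with cumulative enrollment and survey counts."""
    fig, ax1 = plt.subplots(figsize=(9, 4))
    ax1.plot(weekly["week"], 100 * weekly["reporting_rate"], color="tab:blue",
             label="weekly reporting rate (%)")
    ax1.set_xlabel("study week")
    ax1.set_ylabel("reporting rate (%)", color="tab:blue")
    ax1.set_ylim(0, 100)
    ax2 = ax1.twinx()
    ax2.plot(weekly["week"], weekly["n_cumulative"], color="tab:gray",
             linestyle="--", label="N cumulative")
    ax2.plot(weekly["week"], weekly["n_survey"], color="tab:orange",
             linestyle=":", label="N survey")
    ax2.set_ylabel("participants")
    for w in sorted(calendar.maintenance_weeks):
        ax1.axvspan(w - 0.5, w + 0.5, color="0.9", zorder=0)
    fig.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_incidence_vs_reference(flumob_moving, reference_moving_series, calendar,
                                path) -> None:
    """4-week moving proportions of the participatory and sentinel ILI%."""
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(flumob_moving["week"], flumob_moving["moving_pct"],
            label="participatory ILI% (moving)", color="tab:red")
    ax.plot(reference_moving_series.index, reference_moving_series.to_numpy(),
            label="sentinel ILI% (moving)", color="tab:green")
    for w in sorted(calendar.maintenance_weeks):
        ax.axvspan(w - 0.5, w + 0.5, color="0.9", zorder=0)
    ax.set_xlabel("study week")
    ax.set_ylabel("ILI (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
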