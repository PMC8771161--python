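"""Optional figures: training trajectories and PID validation layouts."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .pid_signal import PIDTrace
from .training_analysis import SessionSummary


def plot_training_progress(
    daily: Mapping[object, SessionSummary | float],
    chance: float = 1 / 3,
    criterion: float = 0.85,
):
    """Daily proportion-correct trajectory with chance and criterion lines."""
    days = list(daily)
    values = [
        v.proportion_correct if isinstance(v, SessionSummary) else float(v)
        for v in daily.values()
    ]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(range(1, len(days) + 1), values, "o-", color="black")
    ax.axhline(chance, ls="--", color="gray", label=f"chance ({chance:.2f})")
    ax.axhline(criterion, ls="-", color="gray", label=f"criterion ({criterion:.2f})")
    ax.set_xlabel("Training day")
    ax.set_ylabel("Proportion correct")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_outcome_panels(daily_summaries: Mapping[object, Sequence[SessionSummary]]):
    """Four panels: correct / timeout / false-alert / miss proportions by day."""
    import numpy as np

    days = list(daily_summaries)
    panels = [
        ("Correct", "proportion_correct"),
        ("Timeouts", "proportion_timeout"),
        ("False alerts", "proportion_false_alert"),
        ("Misses", "proportion_miss"),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    for ax, (title, attr) in zip(axes.ravel(), panels):
        values = [
            float(np.mean([getattr(s, attr) for s in daily_summaries[d]]))
            for d in days
        ]
        ax.plot(range(1, len(days) + 1), values, "o-", color="black")
        ax.set_title(title)
        ax.set_ylim(-0.02, 1.02)
    for ax in axes[-1]:
        ax.set_xlabel("Training day")
    fig.tight_layout()
    return fig


def plot_pid_trace(trace: PIDTrace, zoom_epochs: tuple[int, int] | None = None):
    """Full PID record with the valve square wave, plus a zoomed two-epoch
    view when ``zoom_epochs=(start_s, stop_s)`` is given."""
    n_rows = 2 if zoom_epochs else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(9, 3.2 * n_rows), squeeze=False)
    views = [(trace.t_s[0], trace.t_s[-1])] + ([zoom_epochs] if zoom_epochs else [])
    for ax_row, (lo, hi) in zip(axes[:, 0], views):
        mask = (trace.t_s >= lo) & (trace.t_s <= hi)
        ax_row.plot(trace.t_s[mask] / 60, trace.voltage[mask], color="black", lw=0.7)
        vmax = trace.voltage[mask].max() if mask.any() else 1.0
        ax_row.plot(
            trace.t_s[mask] / 60, trace.stim[mask] * vmax, color="red", lw=0.7
        )
        ax_row.set_xlabel("Time (min)")
        ax_row.set_ylabel("PID voltage (V)")
    fig.tight_layout()
    return fig
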