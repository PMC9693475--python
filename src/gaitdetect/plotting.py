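"""Event-overlay plot: angular velocity trace with detected/reference marks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; plots are written to files
import matplotlib.pyplot as plt

from .core import EventLog, GyroSeries

__all__ = ["plot_events_overlay"]

_COLORS = {"MSW": "tab:green", "FS": "tab:blue", "FO": "tab:red"}


def plot_events_overlay(
    series: GyroSeries,
    detected: EventLog,
    reference: EventLog | None = None,
    title: str = "",
    max_seconds: float | None = 12.0,
):
    """Plot the signal with detected events (dashed) and reference (solid)."""
    fig, ax = plt.subplots(figsize=(11, 4))
    t = series.times
    n = len(t) if max_seconds is None else min(len(t), int(max_seconds * series.sampling_rate))
    ax.plot(t[:n], series.samples[:n], color="lightsteelblue", lw=1.2,
            label="angular velocity")
    t_max = t[n - 1] if n else 0.0

    def _marks(log: EventLog, style: str, suffix: str) -> None:
        for kind, color in _COLORS.items():
            times = [e.time_s for e in log.of_kind(kind) if e.time_s <= t_max]
            for i, x in enumerate(times):
                ax.axvline(x, color=color, ls=style, lw=1.0, alpha=0.8,
                           label=f"{kind} {suffix}" if i == 0 else None)

    if reference is not None:
        _marks(reference, "-", "(reference)")
    _marks(detected, "--", "(detected)")
    ax.axhline(0.0, color="gray", lw=0.6)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("angular velocity (rad/s)")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8, ncol=2)
    fig.tight_layout()
    return fig
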