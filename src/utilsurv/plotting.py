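"""Figure-style panels: observed bars, interval bounds, flags, shaded eras.

One panel per (outcome, stratum) cell over the prediction window, in the
style used for surveillance reports: bars for the observed counts, an
upper and a lower prediction-bound line, "+" markers on flagged months,
and grey shading over user-supplied date ranges (e.g. state-of-emergency
periods).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .month import MonthStamp
from .series import Flag, FlagRecord, UtilizationSeries


def build_panel_figure(
    series: UtilizationSeries,
    flags: Sequence[FlagRecord],
    shaded_intervals: Sequence[tuple[MonthStamp, MonthStamp]] = (),
    title: str | None = None,
):
    """Build the panel figure; the caller owns (and must close) it.

    Shaded ranges falling outside the plotted window are clipped silently.
    Marker artists carry labels "deficit"/"excess" so the data layer is
    inspectable.
    """
    if not flags:
        raise ValueError("flags must be non-empty")
    flags = sorted(flags, key=lambda r: r.month)
    x = list(range(len(flags)))
    observed = [r.observed for r in flags]
    lower = [r.lower for r in flags]
    upper = [r.upper for r in flags]

    fig, ax = plt.subplots(figsize=(9, 4))
    first = flags[0].month
    for start, end in shaded_intervals:
        i0 = max(first.months_until(start), -0.5)
        i1 = min(first.months_until(end), len(flags) - 0.5)
        if i1 < -0.5 or i0 > len(flags) - 0.5:
            continue
        ax.axvspan(i0 - 0.5, i1 + 0.5, color="0.85", zorder=0)

    ax.bar(x, observed, color="gold", edgecolor="goldenrod", zorder=2,
           label="observed")
    ax.plot(x, upper, color="tab:blue", lw=1.5, zorder=3, label="upper bound")
    ax.plot(x, lower, color="tab:red", lw=1.5, zorder=3, label="lower bound")

    deficit_x = [i for i, r in enumerate(flags) if r.flag is Flag.DEFICIT]
    excess_x = [i for i, r in enumerate(flags) if r.flag is Flag.EXCESS]
    if deficit_x:
        ax.plot(deficit_x, [flags[i].observed for i in deficit_x], "+",
                color="red", ms=12, mew=2, zorder=4, label="deficit")
    if excess_x:
        ax.plot(excess_x, [flags[i].observed for i in excess_x], "+",
                color="blue", ms=12, mew=2, zorder=4, label="excess")

    ax.set_xticks(x)
    ax.set_xticklabels([r.month.isoformat() for r in flags], rotation=60,
                       ha="right", fontsize=7)
    ax.set_ylabel(series.outcome.value.replace("_", " "))
    ax.set_title(title or f"{series.outcome.value} — {series.stratum}")
    ax.legend(fontsize=7, loc="lower left")
    fig.tight_layout()
    return fig, ax


def render_panel(
    series: UtilizationSeries,
    flags: Sequence[FlagRecord],
    path: str | Path,
    shaded_intervals: Sequence[tuple[MonthStamp, MonthStamp]] = (),
    title: str | None = None,
) -> Path:
    """Render one flag panel to an image file and return its path."""
    fig, _ = build_panel_figure(series, flags, shaded_intervals, title)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
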