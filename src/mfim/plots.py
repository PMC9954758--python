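"""Simple-slopes figures: outcome vs OF index at fixed focal-predictor levels."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .interaction import SimpleSlopes

_LEVEL_COLORS = {"mean-1sd": "tab:blue", "mean": "tab:gray", "mean+1sd": "tab:olive"}


def plot_simple_slopes(
    slopes: SimpleSlopes,
    of_range: tuple[float, float] = (-3.0, 3.0),
    ax=None,
):
    """Draw the three moderation lines; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs = np.linspace(*of_range, 50)
    for label, (level, intercept, slope) in slopes.levels.items():
        ax.plot(xs, intercept + slope * xs,
                color=_LEVEL_COLORS.get(label), label=f"{slopes.predictor} {label}")
    ax.set_xlabel("OF index")
    ax.set_ylabel(slopes.outcome)
    ax.legend()
    return ax


def save_simple_slopes(slopes: SimpleSlopes, path: str | Path, **kwargs) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ax = plot_simple_slopes(slopes, **kwargs)
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
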