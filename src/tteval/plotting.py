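"""Plots: observed curve, prediction-interval band, observation band."""

from __future__ import annotations

import numpy as np

from .interval import PredictionInterval
from .kaplan_meier import KaplanMeierEstimator
from .observation import ObservationBand

__all__ = ["plot_validation"]


def plot_validation(
    observed: KaplanMeierEstimator,
    pi: PredictionInterval,
    band: ObservationBand | None = None,
    ax=None,
    title: str | None = None,
):
    """Observed KM step curve over the 95% prediction interval.

    The prediction interval is drawn as the customary green area; the
    observation variability band, when given, is overlaid hatched.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    t = pi.grid.points
    ax.fill_between(t, pi.lo, pi.hi, color="mediumseagreen", alpha=0.45,
                    label="95% prediction interval", linewidth=0)
    if band is not None:
        ax.fill_between(band.grid, band.lo, band.hi, facecolor="none",
                        edgecolor="steelblue", hatch="///", linewidth=0.0,
                        label="observation band")
    s_obs = observed.predict(t)
    ax.step(t, s_obs, where="post", color="firebrick", label=observed.label or "observed")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("event-free probability")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlim(t[0], t[-1])
    if title:
        ax.set_title(title)
    ax.legend(loc="best", frameon=False)
    return ax
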