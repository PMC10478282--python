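"""Observation-time uncertainty (OTU).

In clinical follow-up an event is only detected at the next scheduled
visit, so the reported time-to-event (RTTE) overstates the true one by at
most the inter-visit delay Δ.  Two devices encode this uncertainty:

* a **deterministic band** between the reported Kaplan–Meier curve and the
  curve with every event shifted earlier by one full Δ — the region in
  which the true curve must lie (used by the juncture metric);
* **random per-patient shifts** ``u ~ U(-Δ, 0)`` applied afresh at every
  bootstrap iteration, for the OTU variants of the statistical tests.

Censored records are administrative and are not moved by the full
deterministic shift; the random per-patient shift applies to every record
of the real cohort, censored or not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SurvivalData
from .kaplan_meier import KaplanMeierEstimator, fit_km

__all__ = [
    "ObservationScheme",
    "ObservationBand",
    "shift_events_full",
    "sample_otu_shift",
    "observation_band",
]


@dataclass(frozen=True)
class ObservationScheme:
    """Observation model: Δ is the inter-visit delay in months (> 0)."""

    otu_width: float

    def __post_init__(self):
        if not self.otu_width > 0:
            raise ValueError("otu_width must be positive")


@dataclass(frozen=True)
class ObservationBand:
    """Pointwise band bounding the reported and fully-shifted curves."""

    grid: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        if not (self.grid.shape == self.lo.shape == self.hi.shape):
            raise ValueError("grid, lo, hi must share one shape")
        if np.any(self.lo > self.hi + 1e-12):
            raise ValueError("band requires lo <= hi pointwise")


def shift_events_full(data: SurvivalData, scheme: ObservationScheme) -> SurvivalData:
    """Shift every *event* earlier by one full OTU, clipping at zero.

    Censored times are left untouched: censoring records the end of
    observation, not a detected event, so the visit-delay argument does
    not apply to it.
    """
    times = data.times.copy()
    times[data.events] = np.maximum(0.0, times[data.events] - scheme.otu_width)
    return SurvivalData(times, data.events.copy(), label=f"{data.label} (-OTU)")


def sample_otu_shift(
    data: SurvivalData, scheme: ObservationScheme, rng: np.random.Generator
) -> SurvivalData:
    """Apply an independent random shift ``u ~ U(-Δ, 0)`` to every record.

    Each real patient receives their own draw; event flags are unchanged
    and shifted times are clipped at zero.  Callers re-draw at every
    bootstrap iteration.
    """
    u = rng.uniform(-scheme.otu_width, 0.0, size=len(data))
    times = np.maximum(0.0, data.times + u)
    return SurvivalData(times, data.events.copy(), label=data.label)


def observation_band(
    reported: KaplanMeierEstimator,
    scheme: ObservationScheme,
    grid: np.ndarray,
) -> ObservationBand:
    """Band between the reported KM curve and its one-OTU-shifted version.

    Parameters
    ----------
    reported : KaplanMeierEstimator
        Fitted curve of the reported cohort; its retained records are
        refitted after the full event shift.
    scheme : ObservationScheme
        Inter-visit delay Δ.
    grid : ndarray
        Evaluation times, all within ``[0, reported.max_follow_up_]``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if grid.min() < 0 or grid.max() > reported.max_follow_up_ + 1e-12:
        raise ValueError("grid outside the reported curve's follow-up range")

    data = SurvivalData(reported.durations_, reported.observed_)
    shifted = fit_km(shift_events_full(data, scheme))

    s_rep = reported.predict(grid)
    s_shift = shifted.predict(grid)
    return ObservationBand(
        grid=grid,
        lo=np.minimum(s_rep, s_shift),
        hi=np.maximum(s_rep, s_shift),
    )
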