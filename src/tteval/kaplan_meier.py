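"""Kaplan–Meier estimation and step-function evaluation.

The product-limit computation is delegated to :mod:`lifelines`; this module
wraps it in a scikit-learn style estimator exposing the risk-table arrays
(event times, at-risk and event counts) that the weighted log-rank and
interval metrics consume, plus fast vectorised right-continuous evaluation.

Conventions
-----------
* Ties between events and censorings at the same time are resolved
  events-first (both are still counted at risk at that time).
* The survival curve is right-continuous: the drop occurs *at* the event
  time, so ``S(t) = P(T > t)``.
* Evaluation beyond the largest follow-up time carries the last value
  forward but is flagged as extrapolation, so metric grids can be
  truncated to the supported range.
"""

from __future__ import annotations

import numpy as np
from lifelines import KaplanMeierFitter
from sklearn.base import BaseEstimator

from .data import SurvivalData, as_survival_data

__all__ = ["KaplanMeierEstimator", "fit_km", "evaluate_km", "median_time"]


class KaplanMeierEstimator(BaseEstimator):
    """Product-limit estimator of the event-free probability.

    Fitted attributes
    -----------------
    event_times_ : ndarray
        Strictly increasing distinct times with at least one event.
    survival_ : ndarray
        Event-free probability immediately after each event time.
    n_at_risk_, n_events_ : ndarray of int
        Risk-set size and number of events at each event time.
    max_follow_up_ : float
        Largest time (event or censoring) in the fitted data.
    durations_, observed_ : ndarray
        Copies of the fitted input, retained so derived curves (e.g. the
        observation-shifted curve) can be refitted from the same records.
    """

    def __init__(self, label: str = "KM"):
        self.label = label

    def fit(self, durations, event_observed=None) -> "KaplanMeierEstimator":
        """Fit the product-limit curve.

        Parameters
        ----------
        durations : SurvivalData or array-like of float
            Either a dataset (``event_observed`` is then ignored) or raw
            times in months.
        event_observed : array-like of bool, optional
            Event indicators when ``durations`` is a raw array; defaults
            to all events.
        """
        if isinstance(durations, SurvivalData):
            data = durations
        else:
            data = SurvivalData(np.asarray(durations, float), event_observed)
        if len(data) == 0:
            raise ValueError("empty dataset")
        if np.min(data.times) < 0:
            raise ValueError("negative time")

        kmf = KaplanMeierFitter()
        kmf.fit(data.times, event_observed=data.events)
        table = kmf.event_table
        is_event = table["observed"].to_numpy() > 0
        times = table.index.to_numpy(float)[is_event]
        surv = kmf.survival_function_["KM_estimate"].to_numpy()[is_event]

        self.durations_ = data.times.copy()
        self.observed_ = data.events.copy()
        self.event_times_ = times
        self.survival_ = surv
        self.n_at_risk_ = table["at_risk"].to_numpy(int)[is_event]
        self.n_events_ = table["observed"].to_numpy(int)[is_event]
        self.max_follow_up_ = float(data.times.max())
        self.n_ = len(data)
        return self

    # -- evaluation -------------------------------------------------------
    def evaluate(self, times):
        """Step-function evaluation with an extrapolation flag.

        Returns ``(probabilities, extrapolated)`` where ``extrapolated``
        marks query times beyond the maximum follow-up (the last value is
        carried forward there).
        """
        times = np.asarray(times, dtype=float)
        if times.size and np.min(times) < 0:
            raise ValueError("negative time")
        idx = np.searchsorted(self.event_times_, times, side="right")
        probs = np.concatenate(([1.0], self.survival_))[idx]
        return probs, times > self.max_follow_up_

    def predict(self, times):
        """Event-free probability at ``times`` (right-continuous steps)."""
        scalar = np.isscalar(times)
        probs, _ = self.evaluate(np.atleast_1d(times))
        return float(probs[0]) if scalar else probs

    @property
    def median_(self) -> float:
        """Smallest event time where the curve falls to 0.5 or below.

        ``nan`` when the curve never reaches 0.5 (e.g. heavy censoring).
        """
        below = self.survival_ <= 0.5
        if not below.any():
            return float("nan")
        return float(self.event_times_[np.argmax(below)])


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_km(data, label: str = "KM") -> KaplanMeierEstimator:
    """Fit a Kaplan–Meier curve to a dataset (array, DataFrame or SurvivalData)."""
    return KaplanMeierEstimator(label=label).fit(as_survival_data(data))


def evaluate_km(curve: KaplanMeierEstimator, t):
    """Right-continuous survival probability of a fitted curve at ``t``."""
    return curve.predict(t)


def median_time(curve: KaplanMeierEstimator) -> float:
    """Median event time of a fitted curve (``nan`` when undefined)."""
    return curve.median_
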