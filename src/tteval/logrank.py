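"""Two-sample weighted log-rank tests, MaxCombo, and a PH diagnostic.

The weighted log-rank statistic compares two survival curves by summing,
over the distinct pooled event times :math:`t_i`, the weighted difference
between the observed and expected number of events in the first group:

.. math::

    U = \\sum_i w_i \\left(d_{1i} - d_i \\frac{n_{1i}}{n_i}\\right),
    \\qquad
    V = \\sum_i w_i^2\\, d_i \\frac{n_{1i}}{n_i}
        \\left(1 - \\frac{n_{1i}}{n_i}\\right) \\frac{n_i - d_i}{n_i - 1},

with :math:`z = U/\\sqrt{V}` referred to a standard normal.  The
Fleming–Harrington family of weights

.. math:: w_i = \\hat S(t_i^-)^{\\rho}\\,(1 - \\hat S(t_i^-))^{\\gamma}

uses the pooled Kaplan–Meier estimate evaluated at the left limit of each
event time; :math:`\\rho, \\gamma \\ge 0` steer the weight towards early
(:math:`\\rho > 0`), middle or late (:math:`\\gamma > 0`) differences.
FH(0, 0) is the classical unweighted log-rank.

The MaxCombo combination runs FH(0,0), FH(1,0), FH(1,1) and FH(0,1),
selects the test with the largest \\|z\\| (the weighting showing the
largest separation between the curves) and applies a Bonferroni factor of
4 to its p-value — a pragmatic guard against the four-fold multiplicity
that stays valid when the hazards are non-proportional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import SurvivalData

__all__ = [
    "FHWeights",
    "LogrankResult",
    "MaxComboResult",
    "PHCheckResult",
    "weighted_logrank",
    "maxcombo",
    "check_ph",
    "MAXCOMBO_WEIGHTS",
]


@dataclass(frozen=True)
class FHWeights:
    """Fleming–Harrington weight exponents ``(rho, gamma)``, both >= 0."""

    rho: float = 0.0
    gamma: float = 0.0

    def __post_init__(self):
        if self.rho < 0 or self.gamma < 0:
            raise ValueError("rho and gamma must be non-negative")

    def __str__(self) -> str:
        return f"FH({self.rho:g},{self.gamma:g})"


#: MaxCombo members in selection (and tie-break) order.
MAXCOMBO_WEIGHTS = (
    FHWeights(0, 0),
    FHWeights(1, 0),
    FHWeights(1, 1),
    FHWeights(0, 1),
)


@dataclass(frozen=True)
class LogrankResult:
    z: float
    chi2: float
    p: float
    weights: FHWeights


@dataclass(frozen=True)
class MaxComboResult:
    per_test: tuple
    selected: int
    p_raw: float
    p_adjusted: float

    @property
    def selected_weights(self) -> FHWeights:
        return self.per_test[self.selected].weights

    @property
    def z(self) -> float:
        return self.per_test[self.selected].z


@dataclass(frozen=True)
class PHCheckResult:
    p: float
    met: bool
    evaluable: bool = True


# ---------------------------------------------------------------------------


def _risk_table(a: SurvivalData, b: SurvivalData):
    """Risk-set tabulation at the distinct pooled event times.

    Returns arrays ``(d, n, d1, n1, s_left)`` where ``s_left`` is the
    pooled Kaplan–Meier survival just before each event time (left limit),
    the evaluation point of the Fleming–Harrington weights.
    """
    times = np.concatenate([a.times, b.times])
    events = np.concatenate([a.events, b.events])
    group_a = np.concatenate(
        [np.ones(len(a), dtype=bool), np.zeros(len(b), dtype=bool)]
    )

    event_times = np.unique(times[events])
    if event_times.size == 0:
        raise ValueError("no events")

    # Risk sets: everyone with time >= t_i, both groups (events-first ties).
    all_sorted = np.sort(times)
    a_sorted = np.sort(times[group_a])
    pooled_ev = np.sort(times[events])
    a_ev = np.sort(times[group_a & events])

    n = (times.size - np.searchsorted(all_sorted, event_times, side="left")).astype(float)
    n1 = (a_sorted.size - np.searchsorted(a_sorted, event_times, side="left")).astype(float)
    d = (
        np.searchsorted(pooled_ev, event_times, side="right")
        - np.searchsorted(pooled_ev, event_times, side="left")
    ).astype(float)
    d1 = (
        np.searchsorted(a_ev, event_times, side="right")
        - np.searchsorted(a_ev, event_times, side="left")
    ).astype(float)

    surv = np.cumprod(1.0 - d / n)          # pooled KM after each event time
    s_left = np.concatenate(([1.0], surv[:-1]))
    return d, n, d1, n1, s_left


def weighted_logrank(
    a: SurvivalData, b: SurvivalData, weights: FHWeights = FHWeights(0, 0)
) -> LogrankResult:
    """Two-sample Fleming–Harrington weighted log-rank test.

    Parameters
    ----------
    a, b : SurvivalData
        The two samples; the statistic is signed with respect to group
        ``a`` (positive z = more events than expected in ``a``).
    weights : FHWeights
        Weight exponents; ``FHWeights(0, 0)`` gives the classical
        unweighted log-rank.

    Notes
    -----
    The hypergeometric variance term is set to zero at risk sets with a
    single subject (``n_i == 1``).  A degenerate all-zero variance yields
    ``z = 0, p = 1`` with a warning.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty dataset")
    d, n, d1, n1, s_left = _risk_table(a, b)

    w = s_left ** weights.rho * (1.0 - s_left) ** weights.gamma
    u = np.sum(w * (d1 - d * n1 / n))
    with np.errstate(invalid="ignore", divide="ignore"):
        var_i = d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1.0)
    var_i = np.where(n > 1, var_i, 0.0)
    v = np.sum(w ** 2 * var_i)

    if v <= 0:
        warnings.warn("zero variance in weighted log-rank; returning z=0, p=1")
        return LogrankResult(z=0.0, chi2=0.0, p=1.0, weights=weights)
    z = u / np.sqrt(v)
    p = 2.0 * stats.norm.sf(abs(z))
    return LogrankResult(z=float(z), chi2=float(z * z), p=float(p), weights=weights)


def maxcombo(a: SurvivalData, b: SurvivalData) -> MaxComboResult:
    """MaxCombo combination of FH(0,0), FH(1,0), FH(1,1), FH(0,1).

    The member with the largest \\|z\\| is selected (ties break towards the
    first in the listed order) and its p-value is Bonferroni-corrected by
    the factor 4: ``p_adjusted = min(1, 4 * p_raw)``.
    """
    results = tuple(weighted_logrank(a, b, w) for w in MAXCOMBO_WEIGHTS)
    abs_z = np.array([abs(r.z) for r in results])
    selected = int(np.argmax(abs_z))  # argmax returns the first maximum
    p_raw = results[selected].p
    return MaxComboResult(
        per_test=results,
        selected=selected,
        p_raw=p_raw,
        p_adjusted=min(1.0, 4.0 * p_raw),
    )


def check_ph(a: SurvivalData, b: SurvivalData, alpha: float = 0.05) -> PHCheckResult:
    """Proportional-hazards diagnostic for the two-group comparison.

    Fits a Cox regression on the group indicator and applies the
    scaled-Schoenfeld-residual score test of proportionality (rank time
    transform).  ``met`` is ``True`` when ``p >= alpha``.

    Degenerate inputs (a group without events, or a fit that does not
    converge) return ``met=True`` with ``evaluable=False`` rather than
    raising, so bootstrap loops can account for them separately.
    """
    if a.n_events == 0 or b.n_events == 0:
        return PHCheckResult(p=float("nan"), met=True, evaluable=False)
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError
    from lifelines.statistics import proportional_hazard_test

    df = pd.DataFrame(
        {
            "time": np.concatenate([a.times, b.times]),
            "event": np.concatenate([a.events, b.events]).astype(int),
            "group": np.concatenate([np.zeros(len(a)), np.ones(len(b))]),
        }
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
            res = proportional_hazard_test(cph, df, time_transform="rank")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return PHCheckResult(p=float("nan"), met=True, evaluable=False)
    p = float(np.asarray(res.p_value).ravel()[0])
    return PHCheckResult(p=p, met=bool(p >= alpha), evaluable=True)
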