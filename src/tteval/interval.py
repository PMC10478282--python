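"""Bootstrapped prediction intervals and the two interval-based metrics.

A deterministic simulation model can be run for an arbitrary number of
virtual patients, so the usual confidence machinery for a single fitted
curve does not apply.  Instead, a *prediction interval* for the simulated
survival curve is built empirically: at each iteration a subsample of the
simulated endpoint pool — the same size as the real cohort — is drawn, its
Kaplan–Meier curve fitted and evaluated on a common time grid; the
pointwise empirical 2.5% and 97.5% quantiles across iterations bound the
95% prediction interval.

Two validation metrics are computed against that band:

* **raw coverage** — the percentage of the observation window where the
  observed KM curve lies inside the prediction interval;
* **juncture** — the percentage of the window where the observation
  variability band (reported curve vs one-OTU-shifted curve) and the
  prediction interval share at least one value.

Both are grid-point counts; on a uniform dense grid they converge to the
time-length ratios used in graphical presentations of the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import SurvivalData, as_survival_data
from .kaplan_meier import KaplanMeierEstimator, fit_km
from .observation import ObservationBand

__all__ = [
    "TimeGrid",
    "PredictionInterval",
    "PredictionIntervalEstimator",
    "build_prediction_interval",
    "raw_coverage",
    "juncture",
]


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing evaluation times spanning ``[0, t_end]``."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            raise ValueError("empty grid")
        if pts.min() < 0:
            raise ValueError("negative time in grid")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @classmethod
    def uniform(cls, t_end: float, n_points: int = 1000) -> "TimeGrid":
        """Uniform grid of ``n_points + 1`` points over ``[0, t_end]``."""
        return cls(np.linspace(0.0, float(t_end), n_points + 1))

    @classmethod
    def from_event_times(cls, pool: SurvivalData, t_end: float | None = None) -> "TimeGrid":
        """Grid at the distinct simulated event times (with t = 0 prepended)."""
        times = np.unique(pool.times[pool.events])
        if t_end is not None:
            times = times[times <= t_end]
        return cls(np.unique(np.concatenate(([0.0], times))))

    def __len__(self) -> int:
        return self.points.size


@dataclass(frozen=True)
class PredictionInterval:
    """Pointwise empirical [2.5%, 97.5%] band of bootstrapped KM curves."""

    grid: TimeGrid
    lo: np.ndarray
    hi: np.ndarray
    n_iter: int
    sample_size: int

    def __post_init__(self):
        if not (len(self.grid) == self.lo.size == self.hi.size):
            raise ValueError("grid, lo, hi must share one length")
        if np.any(self.lo > self.hi + 1e-12):
            raise ValueError("prediction interval requires lo <= hi")
        if np.any(self.lo < -1e-12) or np.any(self.hi > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.grid.points, "lo": self.lo, "hi": self.hi})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def _km_on_grid(times: np.ndarray, events: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Survival of one (possibly censored) sample evaluated on ``grid``."""
    if events.all():
        # No censoring: KM is the empirical survivor function.
        st = np.sort(times)
        return 1.0 - np.searchsorted(st, grid, side="right") / st.size
    curve = fit_km(SurvivalData(times, events))
    return curve.predict(grid)


def build_prediction_interval(
    pool,
    sample_size: int,
    n_iter: int,
    grid: TimeGrid,
    rng: np.random.Generator,
    replace: bool = False,
    q: tuple = (0.025, 0.975),
) -> PredictionInterval:
    """Bootstrap the 95% prediction interval of the simulated curve.

    Parameters
    ----------
    pool : SurvivalData or array of times
        Simulated endpoint pool (one exact predicted time per virtual
        patient; normally all events).
    sample_size : int
        Per-iteration subsample size — chosen equal to the real cohort
        size so each iteration mimics the ongoing study.
    n_iter : int
        Number of bootstrap iterations.
    grid : TimeGrid
        Common evaluation grid.
    rng : numpy Generator
        Source of randomness for the subsampling.
    replace : bool
        Subsample with replacement instead of without (default without:
        a sample is *taken from* the pool; the difference is negligible
        when the pool dwarfs the sample).
    """
    pool = as_survival_data(pool)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not replace and sample_size > len(pool):
        raise ValueError("pool smaller than sample_size")

    pts = grid.points
    curves = np.empty((n_iter, pts.size))
    all_events = bool(pool.events.all())
    for i in range(n_iter):
        idx = rng.choice(len(pool), size=sample_size, replace=replace)
        t = pool.times[idx]
        if all_events:
            st = np.sort(t)
            curves[i] = 1.0 - np.searchsorted(st, pts, side="right") / sample_size
        else:
            curves[i] = _km_on_grid(t, pool.events[idx], pts)

    lo, hi = np.quantile(curves, q, axis=0)
    # Pointwise quantiles of non-increasing step curves are non-increasing;
    # guard against floating-point jitter only.
    lo = np.minimum.accumulate(lo)
    hi = np.minimum.accumulate(hi)
    return PredictionInterval(
        grid=grid, lo=lo, hi=hi, n_iter=n_iter, sample_size=sample_size
    )


class PredictionIntervalEstimator(BaseEstimator):
    """Scikit-learn style wrapper around :func:`build_prediction_interval`.

    Parameters mirror the function; ``fit(pool)`` stores the band in
    ``interval_`` with ``lo_``/``hi_``/``grid_`` aliases.
    """

    def __init__(
        self,
        sample_size: int = 74,
        n_iter: int = 5000,
        grid: TimeGrid | None = None,
        replace: bool = False,
        random_state: int | None = None,
    ):
        self.sample_size = sample_size
        self.n_iter = n_iter
        self.grid = grid
        self.replace = replace
        self.random_state = random_state

    def fit(self, pool, y=None) -> "PredictionIntervalEstimator":
        pool = as_survival_data(pool)
        grid = self.grid or TimeGrid.uniform(pool.max_time)
        rng = np.random.default_rng(self.random_state)
        self.interval_ = build_prediction_interval(
            pool, self.sample_size, self.n_iter, grid, rng, replace=self.replace
        )
        self.grid_ = self.interval_.grid
        self.lo_ = self.interval_.lo
        self.hi_ = self.interval_.hi
        return self

    def score(self, observed) -> float:
        """Raw coverage (in %) of an observed curve or dataset."""
        curve = observed if isinstance(observed, KaplanMeierEstimator) else fit_km(observed)
        return raw_coverage(curve, self.interval_)


# ---------------------------------------------------------------------------
# metrics


def raw_coverage(observed: KaplanMeierEstimator, pi: PredictionInterval) -> float:
    """Percentage of grid points where the observed curve is inside the band.

    The comparison is closed (touching a boundary counts as covered).
    Returns a percentage in [0, 100].
    """
    pts = pi.grid.points
    if pts.size == 0:
        raise ValueError("empty grid")
    s_obs = observed.predict(pts)
    inside = (pi.lo <= s_obs) & (s_obs <= pi.hi)
    return 100.0 * inside.mean()


def juncture(band: ObservationBand, pi: PredictionInterval) -> float:
    """Percentage of grid points where the two intervals overlap.

    At each grid point the observation variability band ``[band.lo,
    band.hi]`` and the prediction interval ``[pi.lo, pi.hi]`` are checked
    for a common value (any partial overlap counts).  Both must be
    evaluated on the same grid.
    """
    if band.grid.shape != pi.grid.points.shape or not np.allclose(
        band.grid, pi.grid.points
    ):
        raise ValueError("band and prediction interval use different grids")
    overlap = (band.lo <= pi.hi) & (pi.lo <= band.hi)
    return 100.0 * overlap.mean()
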