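"""Consolidated six-metric validation of a simulated pool against a cohort.

One fitted :class:`SurvivalModelValidator` computes, with a single master
seed:

==============================  ===========================================
raw_coverage                    % of the window where the observed KM curve
                                lies inside the 95% prediction interval
juncture                        % of the window where the observation band
                                and the prediction interval overlap
boot_logrank / boot_logrank_otu ratio of non-significant bootstrapped
                                log-rank tests, without / with OTU
boot_maxcombo /                 same with the MaxCombo combination
boot_maxcombo_otu               (Bonferroni-adjusted p)
==============================  ===========================================

Every metric is reported in percent and compared (closed boundary) to one
acceptance threshold, 80% by default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bootstrap import BootstrapConfig, bootstrap_test_ratio, verdict
from .data import SurvivalData, as_survival_data
from .interval import TimeGrid, build_prediction_interval, juncture, raw_coverage
from .kaplan_meier import fit_km
from .observation import ObservationScheme, observation_band

__all__ = [
    "METHOD_NAMES",
    "ValidationReport",
    "SurvivalModelValidator",
    "run_validation",
    "compare_subsets",
]

SCHEMA_VERSION = 1

#: The six validation methods, in report order.
METHOD_NAMES = (
    "raw_coverage",
    "juncture",
    "boot_logrank",
    "boot_logrank_otu",
    "boot_maxcombo",
    "boot_maxcombo_otu",
)


def _fingerprint(data: SurvivalData) -> dict:
    payload = np.round(data.times, 9).tobytes() + data.events.tobytes()
    return {
        "n": len(data),
        "n_events": data.n_events,
        "sha1": hashlib.sha1(payload).hexdigest()[:12],
    }


@dataclass
class ValidationReport:
    """Machine-readable twin of a six-row validation table."""

    entries: dict            # method -> {"value": %, "validated": bool, "ph_violation": % or None}
    threshold: float         # percent
    config: dict
    seed: int | None
    inputs: dict
    timestamp: str = ""
    schema_version: int = SCHEMA_VERSION

    @property
    def all_validated(self) -> bool:
        return all(e["validated"] for e in self.entries.values())

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "timestamp": self.timestamp,
            "seed": self.seed,
            "threshold": self.threshold,
            "config": self.config,
            "inputs": self.inputs,
            "entries": self.entries,
        }

    def to_json(self, path=None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path) -> "ValidationReport":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            entries=d["entries"],
            threshold=d["threshold"],
            config=d.get("config", {}),
            seed=d.get("seed"),
            inputs=d.get("inputs", {}),
            timestamp=d.get("timestamp", ""),
            schema_version=d.get("schema_version", SCHEMA_VERSION),
        )

    def to_table(self) -> str:
        lines = [f"{'method':<22}{'metric %':>10}  {'validated':<10}{'PH viol. %':>11}"]
        for name, e in self.entries.items():
            ph = "" if e.get("ph_violation") is None else f"{e['ph_violation']:.2f}"
            lines.append(
                f"{name:<22}{e['value']:>10.2f}  "
                f"{'yes' if e['validated'] else 'NO':<10}{ph:>11}"
            )
        lines.append(f"threshold: {self.threshold:.0f}%")
        return "\n".join(lines)


class SurvivalModelValidator(BaseEstimator):
    """Run all six validation metrics between a simulated pool and a cohort.

    Parameters
    ----------
    n_iter : int
        Bootstrap iterations for the prediction interval and each
        test-based metric.
    alpha : float
        Per-iteration significance level of the tests.
    threshold : float
        Acceptance threshold as a fraction (0.80 = 80%), applied with a
        closed boundary to every metric.
    otu_width : float
        Inter-visit delay Δ in months; drives the juncture band and the
        OTU test variants.
    sample_size : int or None
        Per-iteration pool subsample size (default: cohort size).
    grid_points : int
        Uniform grid resolution over the observation window
        ``[0, min(max follow-up, max simulated time)]``.
    check_ph : bool
        Run the proportional-hazards diagnostic inside the bootstraps.
    random_state : int or None
        Master seed; every stochastic step derives from it.
    """

    def __init__(
        self,
        n_iter: int = 5000,
        alpha: float = 0.05,
        threshold: float = 0.80,
        otu_width: float = 2.0,
        sample_size: int | None = None,
        grid_points: int = 1000,
        check_ph: bool = True,
        random_state: int | None = None,
    ):
        self.n_iter = n_iter
        self.alpha = alpha
        self.threshold = threshold
        self.otu_width = otu_width
        self.sample_size = sample_size
        self.grid_points = grid_points
        self.check_ph = check_ph
        self.random_state = random_state

    def fit(self, pool, observed) -> "SurvivalModelValidator":
        pool = as_survival_data(pool, label="simulated pool")
        observed = as_survival_data(observed, label="observed")
        if len(observed) == 0:
            raise ValueError("empty dataset")
        sample_size = self.sample_size or len(observed)
        scheme = ObservationScheme(self.otu_width)
        master = np.random.SeedSequence(self.random_state)
        streams = [np.random.default_rng(s) for s in master.spawn(5)]

        self.observed_km_ = fit_km(observed, label=observed.label or "observed")
        t_end = min(self.observed_km_.max_follow_up_, pool.max_time)
        grid = TimeGrid.uniform(t_end, self.grid_points)

        self.prediction_interval_ = build_prediction_interval(
            pool, sample_size, self.n_iter, grid, streams[0]
        )
        self.observation_band_ = observation_band(
            self.observed_km_, scheme, grid.points
        )

        metrics: dict[str, float] = {
            "raw_coverage": raw_coverage(self.observed_km_, self.prediction_interval_),
            "juncture": juncture(self.observation_band_, self.prediction_interval_),
        }
        ph: dict[str, float | None] = {"raw_coverage": None, "juncture": None}

        cfg = BootstrapConfig(
            n_iter=self.n_iter,
            alpha=self.alpha,
            threshold=self.threshold,
            sample_size=sample_size,
            check_ph=self.check_ph,
        )
        runs = [
            ("boot_logrank", "logrank", False, streams[1]),
            ("boot_logrank_otu", "logrank", True, streams[2]),
            ("boot_maxcombo", "maxcombo", False, streams[3]),
            ("boot_maxcombo_otu", "maxcombo", True, streams[4]),
        ]
        self.bootstrap_results_ = {}
        for name, test, with_otu, rng in runs:
            res = bootstrap_test_ratio(
                pool, observed, test=test, with_otu=with_otu,
                scheme=scheme, cfg=cfg, rng=rng,
            )
            self.bootstrap_results_[name] = res
            metrics[name] = 100.0 * res.ratio_nonsig
            ph[name] = (
                None if np.isnan(res.ratio_ph_violated)
                else 100.0 * res.ratio_ph_violated
            )

        thr_pct = 100.0 * self.threshold
        entries = {
            name: {
                "value": round(metrics[name], 4),
                "validated": verdict(metrics[name], thr_pct),
                "ph_violation": None if ph[name] is None else round(ph[name], 4),
            }
            for name in METHOD_NAMES
        }
        self.metrics_ = metrics
        self.report_ = ValidationReport(
            entries=entries,
            threshold=thr_pct,
            config={
                "n_iter": self.n_iter,
                "alpha": self.alpha,
                "threshold": self.threshold,
                "otu_width_months": self.otu_width,
                "sample_size": sample_size,
                "grid_points": self.grid_points,
                "check_ph": self.check_ph,
            },
            seed=self.random_state,
            inputs={
                "pool": _fingerprint(pool),
                "observed": _fingerprint(observed),
            },
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )
        self.validated_ = self.report_.all_validated
        return self


def run_validation(pool_csv, observed_csv, config: dict | None = None) -> ValidationReport:
    """Validate a pool CSV against an observed-cohort CSV.

    ``config`` keys (all optional): ``n_iter``, ``alpha``, ``threshold``,
    ``otu_width_months``, ``sample_size``, ``grid_points``, ``check_ph``,
    ``seed``.  Unknown keys raise, naming the offender.
    """
    config = dict(config or {})
    known = {
        "n_iter", "alpha", "threshold", "otu_width_months",
        "sample_size", "grid_points", "check_ph", "seed",
    }
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")

    pool = SurvivalData.read_csv(pool_csv, label="simulated pool")
    observed = SurvivalData.read_csv(observed_csv, label="observed")
    validator = SurvivalModelValidator(
        n_iter=int(config.get("n_iter", 5000)),
        alpha=float(config.get("alpha", 0.05)),
        threshold=float(config.get("threshold", 0.80)),
        otu_width=float(config.get("otu_width_months", 2.0)),
        sample_size=config.get("sample_size"),
        grid_points=int(config.get("grid_points", 1000)),
        check_ph=bool(config.get("check_ph", True)),
        random_state=config.get("seed"),
    ).fit(pool, observed)
    return validator.report_


def compare_subsets(reports: list[ValidationReport], labels: list[str] | None = None) -> pd.DataFrame:
    """Pairwise metric differences between validation reports.

    Returns a DataFrame with one row per method and one signed column per
    ordered pair ``A - B`` (percentage points), mirroring how results on
    population subsets are contrasted against the full cohort.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports")
    methods = list(reports[0].entries)
    for r in reports[1:]:
        if list(r.entries) != methods:
            raise ValueError("reports have mismatched method lists")
    labels = labels or [f"report{i}" for i in range(len(reports))]
    out = {}
    for i, (ri, li) in enumerate(zip(reports, labels)):
        for j, (rj, lj) in enumerate(zip(reports, labels)):
            if i >= j:
                continue
            out[f"{li} - {lj}"] = [
                ri.entries[m]["value"] - rj.entries[m]["value"] for m in methods
            ]
    return pd.DataFrame(out, index=methods)
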