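"""Time-to-event data containers and CSV I/O.

The universal input throughout the package is a labelled collection of
``(time, event)`` pairs: *time* is the elapsed time in months since the
time origin, *event* is ``True`` when the event of interest was observed
and ``False`` when the record is right-censored.

Two kinds of datasets occur in model validation work:

* an **observed cohort** — reported times-to-event (RTTE) from a clinical
  study, typically small and partly censored;
* a **simulated pool** — exact predicted times-to-event (PTTE) produced by
  a deterministic model, one per virtual patient.  Because the model output
  is known at all times, every pool record is an event.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple, Sequence, Union

import numpy as np
import pandas as pd


class TTERecord(NamedTuple):
    """A single subject's follow-up: elapsed time and event indicator."""

    time: float
    event: bool


class SurvivalData:
    """A labelled collection of right-censorable time-to-event records.

    Parameters
    ----------
    times : array-like of float
        Elapsed times in months; must be non-negative.
    events : array-like of bool or 0/1, optional
        Event indicators (``True`` = event observed, ``False`` =
        right-censored).  Defaults to all events, the convention for
        simulated pools where the exact event time is always known.
    label : str
        Free-text label used in reports and plots.
    """

    def __init__(
        self,
        times: Sequence[float],
        events: Sequence[bool] | None = None,
        label: str = "",
    ):
        times = np.asarray(times, dtype=float)
        if times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if times.size and np.min(times) < 0:
            raise ValueError("negative time")
        if events is None:
            events = np.ones(times.shape, dtype=bool)
        else:
            events = np.asarray(events)
            if events.shape != times.shape:
                raise ValueError("times and events must have equal length")
            events = events.astype(bool)
        self.times = times
        self.events = events
        self.label = label

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return self.times.size

    def __iter__(self) -> Iterable[TTERecord]:
        return (TTERecord(t, bool(e)) for t, e in zip(self.times, self.events))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SurvivalData(n={len(self)}, events={self.n_events}, "
            f"label={self.label!r})"
        )

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def max_time(self) -> float:
        if not len(self):
            raise ValueError("empty dataset")
        return float(self.times.max())

    def copy(self, label: str | None = None) -> "SurvivalData":
        return SurvivalData(
            self.times.copy(), self.events.copy(),
            self.label if label is None else label,
        )

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[TTERecord | tuple], label: str = ""
    ) -> "SurvivalData":
        recs = list(records)
        times = [r[0] for r in recs]
        events = [r[1] for r in recs]
        return cls(times, events, label=label)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "SurvivalData":
        missing = {"time", "event"} - set(df.columns)
        if missing:
            raise ValueError(f"missing required column(s): {sorted(missing)}")
        return cls(df["time"].to_numpy(float), df["event"].to_numpy(), label=label)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "event": self.events.astype(int)}
        )

    # -- CSV I/O ----------------------------------------------------------
    @classmethod
    def read_csv(cls, path: Union[str, Path], label: str | None = None) -> "SurvivalData":
        """Read a two-column ``time,event`` CSV (header required, UTF-8)."""
        path = Path(path)
        df = pd.read_csv(path, encoding="utf-8")
        bad = df["time"].isna() if "time" in df.columns else None
        if bad is not None and bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"malformed CSV {path}: unparseable time at row {row}")
        return cls.from_dataframe(df, label=path.stem if label is None else label)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, index=False, encoding="utf-8")


def as_survival_data(obj, label: str = "") -> SurvivalData:
    """Coerce an array of times, a DataFrame or a SurvivalData instance."""
    if isinstance(obj, SurvivalData):
        return obj
    if isinstance(obj, pd.DataFrame):
        return SurvivalData.from_dataframe(obj, label=label)
    return SurvivalData(np.asarray(obj, dtype=float), label=label)
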