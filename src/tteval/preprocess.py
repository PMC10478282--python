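"""Deriving time-to-progression (TTP) from PFS and OS event lists.

Progression-free survival (PFS) counts both disease progression and death
as events, while a tumour-growth model typically predicts time to
progression only (death is censored out).  When per-patient linkage is
lost — e.g. the event lists were digitised from published Kaplan–Meier
figures — deaths occurring before progression can still be filtered out
under one assumption: such a patient contributes the *same* time to both
the PFS and OS lists.  PFS events that match an OS event within a small
tolerance (manual-extraction uncertainty; 2 days by default) are therefore
removed as deaths, censored PFS records are dropped, and the remainder is
the TTP event list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SurvivalData

__all__ = ["DerivationReport", "derive_ttp", "DAYS_PER_MONTH"]

#: Mean Gregorian month length used for day -> month conversion.
DAYS_PER_MONTH = 30.4375


@dataclass
class DerivationReport:
    """Accounting of the PFS -> TTP derivation.

    ``n_input_pfs == n_censored_removed + n_death_removed + n_ttp`` always.
    ``ambiguous`` lists PFS times that had more than one OS event within
    tolerance (the matcher picks the nearest, earliest on ties, but such
    cases deserve a look).
    """

    n_input_pfs: int
    n_censored_removed: int
    n_death_removed: int
    n_ttp: int
    matched_pairs: list = field(default_factory=list)
    ambiguous: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_pfs": self.n_input_pfs,
            "n_censored_removed": self.n_censored_removed,
            "n_death_removed": self.n_death_removed,
            "n_ttp": self.n_ttp,
            "matched_pairs": [list(p) for p in self.matched_pairs],
            "ambiguous": list(self.ambiguous),
        }


def derive_ttp(
    pfs: SurvivalData,
    os_data: SurvivalData,
    tolerance_days: float = 2.0,
) -> tuple[SurvivalData, DerivationReport]:
    """Filter deaths-before-progression out of a PFS event list.

    Parameters
    ----------
    pfs, os_data : SurvivalData
        Digitised PFS and OS lists, times in months.  Only OS *events*
        participate in matching.
    tolerance_days : float
        Two times are considered equal when they differ by at most this
        many days (converted at 30.4375 days/month).

    Returns
    -------
    (ttp, report)
        ``ttp`` contains the remaining PFS events (all ``event=True``);
        the report gives removal counts and the matched (PFS, OS) pairs.

    Notes
    -----
    Matching is one-to-one and greedy: PFS events are processed in
    ascending time; each is matched to the nearest still-unused OS event
    within tolerance (ties resolve to the earliest OS time).  The result
    is deterministic and independent of input record order.
    """
    if len(pfs) == 0:
        raise ValueError("empty PFS dataset")
    tol = tolerance_days / DAYS_PER_MONTH

    n_input = len(pfs)
    pfs_events = np.sort(pfs.times[pfs.events])
    n_censored = int(n_input - pfs_events.size)

    os_events = np.sort(os_data.times[os_data.events]) if len(os_data) else np.array([])
    os_used = np.zeros(os_events.size, dtype=bool)

    kept, pairs, ambiguous = [], [], []
    for t in pfs_events:
        if os_events.size:
            gap = np.abs(os_events - t)
            eligible = (gap <= tol) & ~os_used
        else:
            eligible = np.zeros(0, dtype=bool)
        if eligible.any():
            cand = np.flatnonzero(eligible)
            if cand.size > 1:
                ambiguous.append(float(t))
            # nearest OS event; np.argmin takes the first (= earliest) on ties
            j = cand[np.argmin(gap[cand])]
            os_used[j] = True
            pairs.append((float(t), float(os_events[j])))
        else:
            kept.append(float(t))

    ttp = SurvivalData(np.array(kept), label="TTP")
    report = DerivationReport(
        n_input_pfs=n_input,
        n_censored_removed=n_censored,
        n_death_removed=len(pairs),
        n_ttp=len(kept),
        matched_pairs=pairs,
        ambiguous=ambiguous,
    )
    return ttp, report
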