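"""Independent brute-force oracles used across the test suite.

These deliberately use plain Python loops and their own pooled KM
bookkeeping so they share no code path with the package implementation.
"""

import math


def brute_force_weighted_logrank(times_a, events_a, times_b, events_b,
                                 rho=0.0, gamma=0.0):
    """Per-risk-set tabulation of the FH-weighted log-rank z statistic.

    Walks the distinct pooled event times in order, counting risk sets and
    events by exhaustive enumeration, with the pooled product-limit
    survival tracked by hand for the left-limit weights.
    """
    recs = [(float(t), bool(e), 0) for t, e in zip(times_a, events_a)]
    recs += [(float(t), bool(e), 1) for t, e in zip(times_b, events_b)]
    event_times = sorted({t for t, e, _ in recs if e})
    assert event_times, "oracle needs at least one event"

    s_pool = 1.0  # pooled KM just before the current event time
    u = 0.0
    v = 0.0
    for t in event_times:
        n = sum(1 for tt, _, _ in recs if tt >= t)
        n1 = sum(1 for tt, _, g in recs if tt >= t and g == 0)
        d = sum(1 for tt, e, _ in recs if tt == t and e)
        d1 = sum(1 for tt, e, g in recs if tt == t and e and g == 0)
        w = (s_pool ** rho) * ((1.0 - s_pool) ** gamma)
        u += w * (d1 - d * n1 / n)
        if n > 1:
            v += w * w * d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1)
        s_pool *= 1.0 - d / n
    return u / math.sqrt(v) if v > 0 else 0.0


def empirical_survivor_fraction(times, t):
    """Brute-force survivor fraction P(T > t) for event-only data."""
    times = list(times)
    return sum(1 for x in times if x > t) / len(times)
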