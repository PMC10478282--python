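import dataclasses

import numpy as np
import pytest

from conftest import random_survival_data
from helpers import brute_force_weighted_logrank
from tteval import (
    FHWeights,
    SurvivalData,
    check_ph,
    get_scenario,
    maxcombo,
    simulate_trial,
    weighted_logrank,
)
from tteval.logrank import MAXCOMBO_WEIGHTS, _risk_table


@pytest.fixture
def spec_pair():
    a = SurvivalData([6, 7, 10, 9], [1, 1, 1, 0])
    b = SurvivalData([1, 3, 4, 5], [1, 1, 1, 1])
    return a, b


class TestWeightedLogrank:
    def test_identical_groups_give_zero(self):
        d = SurvivalData([2, 4, 6, 8], [1, 1, 0, 1])
        r = weighted_logrank(d, d.copy())
        assert r.z == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_swapping_groups_flips_sign(self, spec_pair):
        a, b = spec_pair
        r1 = weighted_logrank(a, b)
        r2 = weighted_logrank(b, a)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_hand_tabulated_example(self, spec_pair):
        a, b = spec_pair
        z_oracle = brute_force_weighted_logrank(
            a.times, a.events, b.times, b.events
        )
        r = weighted_logrank(a, b)
        assert r.z == pytest.approx(z_oracle, abs=1e-12)
        assert r.chi2 == pytest.approx(r.z**2)

    @pytest.mark.parametrize("rho,gamma", [(0, 0), (1, 0), (1, 1), (0, 1), (2, 0.5)])
    def test_matches_brute_force_all_weights(self, rng, rho, gamma):
        for _ in range(10):
            a = random_survival_data(rng)
            b = random_survival_data(rng)
            z_oracle = brute_force_weighted_logrank(
                a.times, a.events, b.times, b.events, rho, gamma
            )
            r = weighted_logrank(a, b, FHWeights(rho, gamma))
            assert r.z == pytest.approx(z_oracle, abs=1e-10)

    def test_matches_lifelines_fleming_harrington(self, rng):
        """Cross-check against an established FH log-rank implementation."""
        from lifelines.statistics import logrank_test

        for rho, gamma in [(0, 0), (1, 0), (1, 1), (0, 1)]:
            a = random_survival_data(rng)
            b = random_survival_data(rng)
            r = weighted_logrank(a, b, FHWeights(rho, gamma))
            if (rho, gamma) == (0, 0):
                ll = logrank_test(a.times, b.times, a.events, b.events)
            else:
                ll = logrank_test(
                    a.times, b.times, a.events, b.events,
                    weightings="fleming-harrington", p=rho, q=gamma,
                )
            assert r.chi2 == pytest.approx(float(ll.test_statistic), rel=1e-9)

    def test_no_events_raises(self):
        a = SurvivalData([1, 2], [0, 0])
        b = SurvivalData([3], [0])
        with pytest.raises(ValueError, match="no events"):
            weighted_logrank(a, b)

    def test_zero_variance_returns_null_result_with_warning(self):
        # both subjects fail at the same single time: hypergeometric
        # variance term vanishes (n == d)
        a = SurvivalData([5.0])
        b = SurvivalData([5.0])
        with pytest.warns(UserWarning, match="zero variance"):
            r = weighted_logrank(a, b)
        assert r.z == 0.0 and r.p == 1.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            FHWeights(-1, 0)

    def test_weight_monotonicity_along_event_times(self, rng):
        """FH(1,0) weights fall over time, FH(0,1) weights rise."""
        a = random_survival_data(rng, n_max=25)
        b = random_survival_data(rng, n_max=25)
        *_, s_left = _risk_table(a, b)
        w_early = s_left**1  # FH(1,0)
        w_late = 1 - s_left  # FH(0,1)
        assert np.all(np.diff(w_early) <= 1e-12)
        assert np.all(np.diff(w_late) >= -1e-12)


class TestMaxCombo:
    def test_identical_groups(self):
        d = SurvivalData([1, 2, 3, 4.5], [1, 1, 1, 1])
        res = maxcombo(d, d.copy())
        assert all(r.z == pytest.approx(0, abs=1e-12) for r in res.per_test)
        assert res.p_adjusted == 1.0
        assert res.selected == 0  # tie broken to the first listed test

    def test_bonferroni_adjustment(self, spec_pair):
        res = maxcombo(*spec_pair)
        assert res.p_adjusted == pytest.approx(min(1.0, 4 * res.p_raw))
        assert res.p_adjusted >= res.p_raw
        assert res.per_test[res.selected].weights == MAXCOMBO_WEIGHTS[res.selected]

    def test_selects_largest_absolute_z(self, rng):
        a = random_survival_data(rng)
        b = random_survival_data(rng)
        res = maxcombo(a, b)
        assert abs(res.per_test[res.selected].z) == pytest.approx(
            max(abs(r.z) for r in res.per_test)
        )

    def test_late_difference_favours_late_weights(self, rng):
        """With a late-only hazard difference FH(0,1) wins most replicates."""
        sc = get_scenario("late_difference")
        null_sc = get_scenario("null")
        wins = 0
        n_rep = 60
        for _ in range(n_rep):
            a, _ = simulate_trial(dataclasses.replace(sc, seed=None), rng=rng)
            b, _ = simulate_trial(dataclasses.replace(null_sc, seed=None), rng=rng)
            res = maxcombo(a, b)
            wins += res.selected_weights == FHWeights(0, 1)
        assert wins > n_rep / 2


class TestPHCheck:
    def test_identical_datasets_non_significant(self):
        d = SurvivalData(np.linspace(1, 20, 30))
        res = check_ph(d, d.copy())
        assert res.evaluable and res.met
        assert res.p > 0.05

    def test_null_exponential_rarely_flags(self, rng):
        met = 0
        n_rep = 40
        for _ in range(n_rep):
            a = SurvivalData(rng.exponential(12, 60))
            b = SurvivalData(rng.exponential(12, 60))
            met += check_ph(a, b).met
        # nominal rate of spurious violation is alpha = 5%
        assert met / n_rep >= 0.85

    def test_crossing_hazards_flagged(self, rng):
        """Reversing hazard ratios violate proportionality detectably."""
        from tteval import PiecewiseExponential

        up = PiecewiseExponential(rates=(0.05, 0.30), breaks=(8.0,))
        down = PiecewiseExponential(rates=(0.30, 0.05), breaks=(8.0,))
        flagged = 0
        n_rep = 20
        for _ in range(n_rep):
            a = SurvivalData(up.sample(150, rng))
            b = SurvivalData(down.sample(150, rng))
            flagged += not check_ph(a, b).met
        assert flagged > n_rep / 2

    def test_degenerate_group_not_evaluable(self):
        a = SurvivalData([1, 2, 3], [0, 0, 0])
        b = SurvivalData([1, 2, 3], [1, 1, 1])
        res = check_ph(a, b)
        assert not res.evaluable and res.met
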