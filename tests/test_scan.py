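import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seasonscan.series import OESeries
from seasonscan.scan import (Window, enumerate_windows, monte_carlo_p,
                             most_likely_cluster, scan, window_llr)

from conftest import random_series


def brute_force_scan(observed, expected, max_len=6):
    """Independent oracle: plain loops and math.log over every candidate."""
    o_tot, e_tot = float(sum(observed)), float(sum(expected))

    def xlx(o, e):
        return o * math.log(o / e) if o > 0 else 0.0

    best = None
    for length in range(1, max_len + 1):
        for start in range(1, 13):
            members = [(start - 1 + k) % 12 for k in range(length)]
            o_in = float(sum(observed[i] for i in members))
            e_in = float(sum(expected[i] for i in members))
            llr = xlx(o_in, e_in) + xlx(o_tot - o_in, e_tot - e_in) - xlx(o_tot, e_tot)
            if best is None or llr > best[0] + 1e-12:
                best = (llr, start, length)
    return best


class TestWindows:
    def test_candidate_count(self):
        assert len(enumerate_windows(6)) == 72
        assert len(enumerate_windows(1)) == 12

    def test_wraparound_membership(self):
        assert Window(11, 4).members() == [11, 12, 1, 2]
        assert 1 in Window(11, 4)
        assert 3 not in Window(11, 4)

    def test_window_and_complement_partition_the_loop(self):
        w = Window(9, 5)
        assert sorted(w.members() + w.complement().members()) == list(range(1, 13))

    def test_labels(self):
        assert Window(3, 2).label() == "Mar-Apr"
        assert Window(10, 1).label() == "Oct"
        assert Window(12, 2).label() == "Dec-Jan"
        assert Window(12, 1).label(scheme="midmonth") == "15 Dec-14 Jan"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enumerate_windows(12)
        with pytest.raises(ValueError):
            Window(0, 2)


class TestWindowLLR:
    def test_zero_when_rates_match(self):
        assert window_llr(50, 50.0, 600, 600.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_deficit_window(self):
        # two-month deficit: 74 observed vs 90.6 expected out of 541
        got = window_llr(74, 90.6, 541, 541.0)
        o_out, e_out = 541 - 74, 541 - 90.6
        want = 74 * math.log(74 / 90.6) + o_out * math.log(o_out / e_out)
        assert got == pytest.approx(want)
        assert got == pytest.approx(1.925, abs=0.01)

    @given(o_in=st.integers(0, 200), o_rest=st.integers(0, 500),
           e_in=st.floats(1.0, 200.0), e_rest=st.floats(1.0, 500.0))
    @settings(max_examples=200, deadline=None)
    def test_nonnegative_everywhere(self, o_in, o_rest, e_in, e_rest):
        llr = window_llr(o_in, e_in, o_in + o_rest, e_in + e_rest)
        assert llr >= 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            window_llr(5, 0.0, 10, 10.0)
        with pytest.raises(ValueError):
            window_llr(11, 5.0, 10, 10.0)


class TestMostLikelyCluster:
    def test_equals_brute_force_on_random_series(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            s = random_series(rng)
            got = most_likely_cluster(s)
            llr, start, length = brute_force_scan(list(s.observed), list(s.expected))
            assert got.llr == pytest.approx(llr, abs=1e-12)
            assert (got.window.start, got.window.length) == (start, length)

    def test_flat_series_ties_break_to_first_single_month(self):
        s = OESeries(np.full(12, 50), np.full(12, 50.0))
        res = most_likely_cluster(s)
        assert res.llr == pytest.approx(0.0, abs=1e-12)
        assert (res.window.start, res.window.length) == (1, 1)

    def test_adding_cases_to_a_high_window_never_lowers_the_maximum(self):
        rng = np.random.default_rng(22)
        s = random_series(rng)
        res = most_likely_cluster(s)
        if res.direction != "high":  # force a high cluster to exist
            o = s.observed.copy()
            o[res.window.start - 1] += 30
            s = OESeries(o, s.expected)
            res = most_likely_cluster(s)
        prev = res.llr
        for extra in range(1, 6):
            o = s.observed.copy()
            for m in res.window.members():
                o[m - 1] += extra
            new = most_likely_cluster(OESeries(o, s.expected))
            assert new.llr >= prev - 1e-12
            prev = new.llr

    def test_direction_flags_deficits(self, neuro_series):
        obs = neuro_series.observed.copy()
        obs[4] = 40  # carve a deficit into May
        res = most_likely_cluster(OESeries(obs, neuro_series.expected))
        assert res.direction == "low"
        assert 5 in res.window.members()


class TestMonteCarlo:
    def test_p_in_admissible_range_and_reproducible(self, neuro_series):
        res = most_likely_cluster(neuro_series)
        p1 = monte_carlo_p(neuro_series, res.llr, nsim=999, seed=5)
        p2 = monte_carlo_p(neuro_series, res.llr, nsim=999, seed=5)
        assert p1 == p2
        assert 1 / 1000 <= p1 <= 1.0

    def test_zero_statistic_gives_p_one(self, neuro_series):
        assert monte_carlo_p(neuro_series, 0.0, nsim=999, seed=1) == 1.0

    def test_extreme_cluster_attains_the_minimum_p(self):
        o = np.zeros(12, int)
        o[6] = 500
        s = OESeries(o, np.full(12, 500 / 12))
        res = most_likely_cluster(s)
        p = monte_carlo_p(s, res.llr, nsim=999, seed=3)
        assert p == pytest.approx(1 / 1000)

    def test_scan_records_its_provenance(self, neuro_series):
        res = scan(neuro_series, nsim=199, seed=9)
        assert res.nsim == 199 and res.seed == 9
        assert res.p_value is not None
        assert res.o_in + res.o_out == neuro_series.total_observed
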