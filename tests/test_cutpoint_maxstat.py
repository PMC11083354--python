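import numpy as np
import pytest

from nichecontact import (
    ValidationError,
    candidate_cutpoints,
    logrank_standardized,
    maxstat_cutpoint,
    maxstat_test,
    mc_adjusted_p,
    simulate_step_cohort,
)
from nichecontact.cutpoint_maxstat import maxstat_scan

from oracles import logrank_table

# perfectly separated toy data: the low-x group dies at 1, 2, 3 while the
# high-x group dies at 10, 11, 12
TOY_X = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
TOY_T = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
TOY_E = np.ones(6, dtype=bool)


class TestCandidates:
    def test_enumeration_within_bounds(self):
        x = np.arange(1, 11)
        np.testing.assert_array_equal(candidate_cutpoints(x, 0.1, 0.9),
                                      np.arange(1, 10))

    def test_all_equal_errors(self):
        with pytest.raises(ValidationError):
            candidate_cutpoints(np.ones(10))

    def test_ties_match_brute_force_filter(self):
        rng = np.random.default_rng(2)
        x = rng.choice([1.0, 2.0, 3.0, 4.0, 5.0], size=50)
        got = candidate_cutpoints(x, 0.1, 0.9)
        expect = sorted(v for v in np.unique(x)
                        if 0.1 <= np.mean(x <= v) <= 0.9)
        np.testing.assert_array_equal(got, expect)

    def test_invalid_bounds(self):
        with pytest.raises(ValidationError):
            candidate_cutpoints(np.arange(10), 0.9, 0.1)


class TestLogrank:
    def test_exchangeable_groups_give_zero(self):
        # paired identical observations split evenly across groups
        times = np.array([2.0, 2.0, 5.0, 5.0, 9.0, 9.0])
        events = np.array([True, True, True, True, False, False])
        group = np.array([True, False, True, False, True, False])
        assert logrank_standardized(times, events, group) == pytest.approx(0.0, abs=1e-12)

    def test_separated_toy_matches_risk_set_table(self):
        group = TOY_X <= 3
        o, e, v = logrank_table(TOY_T, TOY_E, group)
        # 6 risk sets: O = 3, E = 3/6 + 2/5 + 1/4, V = accumulated
        assert (o, e) == (3.0, pytest.approx(1.15))
        z = logrank_standardized(TOY_T, TOY_E, group)
        assert z == pytest.approx((o - e) / np.sqrt(v), abs=1e-12)
        assert z == pytest.approx(2.2476, abs=1e-4)

    def test_sign_convention_earlier_deaths(self):
        group_late = TOY_X > 3       # the other group relative to early deaths
        assert logrank_standardized(TOY_T, TOY_E, group_late) < 0
        assert logrank_standardized(TOY_T, TOY_E, ~group_late) > 0

    def test_degenerate_grouping_errors(self):
        with pytest.raises(ValidationError):
            logrank_standardized(TOY_T, TOY_E, np.ones(6, dtype=bool))


class TestMaxstatCutpoint:
    def test_toy_maximum_matches_exhaustive_scan(self):
        # exhaustive per-candidate standardized log-rank values, from the
        # independent risk-set-table oracle over the 5 admissible candidates:
        # |Z(1)| = 2.2361, |Z(2)| = 2.3724, |Z(3)| = 2.2476, |Z(10)| = 1.9655,
        # |Z(11)| = 1.4810 -> the maximum sits at mu = 2
        mu, m, per = maxstat_cutpoint(TOY_X, TOY_T, TOY_E)
        expected = {}
        for cand in (1.0, 2.0, 3.0, 10.0, 11.0):
            o, e, v = logrank_table(TOY_T, TOY_E, TOY_X <= cand)
            expected[cand] = abs(o - e) / np.sqrt(v)
        assert mu == max(expected, key=expected.get) == 2.0
        assert m == pytest.approx(expected[2.0], abs=1e-10)
        assert per.shape == (5, 1 + 1)
        np.testing.assert_allclose(np.abs(per[:, 1]),
                                   [expected[c] for c in (1, 2, 3, 10, 11)],
                                   atol=1e-10)

    def test_scan_matches_single_split_statistic(self, rng):
        n = 60
        x = rng.uniform(0, 10, n)
        t = rng.exponential(5, n)
        e = rng.random(n) < 0.8
        cands = candidate_cutpoints(x)
        scan = maxstat_scan(x, t, e, cands)
        direct = [logrank_standardized(t, e, x <= mu) for mu in cands]
        np.testing.assert_allclose(scan, direct, atol=1e-10)

    def test_monotone_relabeling_invariance(self, rng):
        n = 80
        x = rng.uniform(0, 20, n)
        t = rng.exponential(6, n)
        e = rng.random(n) < 0.7
        mu1, m1, per1 = maxstat_cutpoint(x, t, e)
        mu2, m2, per2 = maxstat_cutpoint(2 * x + 1, t, e)
        assert m2 == pytest.approx(m1, abs=1e-10)
        assert mu2 == pytest.approx(2 * mu1 + 1)
        np.testing.assert_allclose(per2[:, 1], per1[:, 1], atol=1e-10)


class TestMCAdjustment:
    def test_fixed_seed_is_deterministic(self, rng):
        x = rng.uniform(0, 10, 40)
        t = rng.exponential(5, 40)
        e = np.ones(40, dtype=bool)
        p1 = mc_adjusted_p(x, t, e, B=199, seed=7)
        p2 = mc_adjusted_p(x, t, e, B=199, seed=7)
        assert p1 == p2

    def test_lower_bound_when_observed_dominates(self):
        # perfectly monotone covariate-survival association at n=40: no
        # permutation beats the observed maximum, so p hits its floor
        n = 40
        x = np.arange(1.0, n + 1)
        p = mc_adjusted_p(x, x, np.ones(n, bool), B=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_invariant_to_subject_order(self, rng):
        n = 50
        x = rng.uniform(0, 10, n)
        t = rng.exponential(5, n)
        e = rng.random(n) < 0.8
        perm = rng.permutation(n)
        p1 = mc_adjusted_p(x, t, e, B=199, seed=3)
        p2 = mc_adjusted_p(x[perm], t[perm], e[perm], B=199, seed=3)
        assert p1 == p2

    def test_naive_minimum_p_is_anticonservative_on_null(self):
        from scipy import stats
        naive, adjusted = [], []
        for s in range(100):
            df = simulate_step_cohort(n=100, hazard_ratio=1.0, seed=s)
            mu, m, per = maxstat_cutpoint(df.x, df.os_months, df.event)
            naive.append(2 * stats.norm.sf(np.abs(per[:, 1])).min())
            adjusted.append(mc_adjusted_p(df.x, df.os_months, df.event,
                                          B=99, seed=s))
        naive, adjusted = np.array(naive), np.array(adjusted)
        assert (adjusted >= naive).mean() > 0.95
        assert (naive <= 0.05).mean() > (adjusted <= 0.05).mean()

    def test_maxstat_test_bundles_result(self):
        res = maxstat_test(TOY_X, TOY_T, TOY_E, B=99, seed=1)
        assert res.cutpoint == 2.0
        assert res.n_candidates == 5
        assert 0 < res.p_adjusted <= 1
        assert res.settings["replicates"] == 99
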