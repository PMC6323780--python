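import math

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

import ccmpipe as cp

from conftest import make_series


# ---------------------------------------------------------------------------
# ghost filtering


def ghost_oracle(counts, gap=720):
    """Independent left-to-right enumeration of the isolation rule."""
    nz = [i for i, c in enumerate(counts) if c > 0]
    ghosts, last = [], None
    for k, i in enumerate(nz):
        nxt = nz[k + 1] if k + 1 < len(nz) else None
        before = last is not None and i - last > gap
        after = nxt is None or nxt - i > gap
        if before and after:
            ghosts.append(i)
        else:
            last = i
    return ghosts


class TestFilterGhosts:
    def test_isolated_count_13h_after_activity_removed(self):
        counts = np.zeros(22000, dtype=int)
        counts[0:20001:10] = 1  # activity every 10 min up to minute 20000
        counts[20800] = 1  # 13.3 h later, isolated
        filtered, ghosts = cp.filter_ghosts(make_series(counts))
        assert ghosts == [20800]
        assert filtered.counts[20800] == 0

    def test_count_11h_after_activity_retained(self):
        counts = np.zeros(2000, dtype=int)
        counts[0] = 1
        counts[660] = 1  # 11 h gap: below threshold
        _, ghosts = cp.filter_ghosts(make_series(counts))
        assert ghosts == []

    def test_paired_late_counts_both_retained(self):
        counts = np.zeros(23000, dtype=int)
        counts[20000] = 1
        counts[20780] = 1  # 13 h after previous activity ...
        counts[20810] = 1  # ... but only 30 min apart: not isolated
        filtered, ghosts = cp.filter_ghosts(make_series(counts))
        assert ghosts == []
        assert filtered.counts[20780] == 1 and filtered.counts[20810] == 1

    def test_matches_enumeration_oracle_on_random_series(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            counts = np.zeros(4000, dtype=int)
            counts[rng.choice(4000, size=rng.integers(1, 8), replace=False)] = 1
            _, ghosts = cp.filter_ghosts(make_series(counts))
            assert ghosts == ghost_oracle(counts)

    def test_never_increases_lifespan(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            counts = np.zeros(3000, dtype=int)
            counts[rng.choice(3000, size=5, replace=False)] = 1
            series = make_series(counts)
            filtered, ghosts = cp.filter_ghosts(series)
            before = np.flatnonzero(series.counts)[-1]
            after = np.flatnonzero(filtered.counts)[-1]
            assert after <= before

    def test_dense_series_untouched(self):
        counts = np.ones(3000, dtype=int)
        filtered, ghosts = cp.filter_ghosts(make_series(counts))
        assert ghosts == []
        assert np.array_equal(filtered.counts, counts)


class TestCallDeath:
    def test_last_beam_break_defines_lifespan(self):
        counts = np.zeros(2000, dtype=int)
        counts[0] = 1
        counts[1440] = 2
        rec = cp.call_death(make_series(counts))
        assert rec.lifespan_minutes == 1440
        assert rec.lifespan_days == pytest.approx(1.0)
        assert rec.event

    def test_nonzero_final_bin(self):
        counts = np.ones(100, dtype=int)
        assert cp.call_death(make_series(counts)).lifespan_minutes == 99

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError, match="no beam breaks"):
            cp.call_death(make_series(np.zeros(100, dtype=int)))


# ---------------------------------------------------------------------------
# survival estimators


class TestKaplanMeier:
    def test_uncensored_drops_one_nth_per_event(self):
        fit = cp.km_fit([1.0, 2.0, 3.0, 4.0, 5.0])
        drops = np.diff(np.r_[1.0, fit.survival[1:]])
        assert np.allclose(drops, -0.2)
        assert fit.median == 3.0  # ceil(n/2)-th order statistic

    def test_even_n_median_at_half_survival(self):
        assert cp.km_fit([1.0, 2.0, 3.0, 4.0]).median == 2.0

    def test_exponential_median_matches_closed_form(self):
        rng = np.random.default_rng(5)
        scale = 20.0
        fit = cp.km_fit(rng.exponential(scale, size=20000))
        expected = math.log(2) * scale
        assert fit.median == pytest.approx(expected, rel=0.03)

    def test_single_fly_steps_to_zero(self):
        fit = cp.km_fit([7.0])
        assert fit.survival[-1] == 0.0
        assert fit.median == 7.0

    def test_survival_monotone_from_one(self):
        rng = np.random.default_rng(9)
        fit = cp.km_fit(rng.exponential(10, 50))
        assert fit.survival[0] == 1.0
        assert (np.diff(fit.survival) <= 1e-12).all()

    def test_all_censored_median_undefined(self):
        fit = cp.km_fit([1.0, 2.0, 3.0, 4.0], events=[False] * 4)
        assert math.isinf(fit.median)


def logrank_oracle(a, b):
    """Hand implementation of the two-group log-rank statistic (1 df)."""
    times = sorted(set(a) | set(b))
    O = E = V = 0.0
    for t in times:
        na = sum(x >= t for x in a)
        nb = sum(x >= t for x in b)
        da = a.count(t)
        d = da + b.count(t)
        n = na + nb
        if n < 1 or d == 0:
            continue
        O += da
        E += d * na / n
        if n > 1:
            V += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_give_null(self):
        stat, p = cp.logrank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 20.0, 30.0]
        stat, p = cp.logrank_test(a, b)
        expected = logrank_oracle(a, b)
        assert stat == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-9)

    def test_symmetric_under_label_swap(self):
        a, b = [3.0, 5.0, 8.0, 9.0], [2.0, 4.0, 6.0]
        assert cp.logrank_test(a, b)[0] == pytest.approx(cp.logrank_test(b, a)[0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cp.logrank_test([], [1.0])


def cox_partial_loglik(beta, durations, events, z):
    """Breslow/Efron partial log-likelihood (no ties in this fixture)."""
    order = np.argsort(durations)
    d = np.asarray(durations)[order]
    e = np.asarray(events)[order]
    zz = np.asarray(z)[order]
    ll = 0.0
    for i in range(len(d)):
        if not e[i]:
            continue
        at_risk = d >= d[i]
        ll += beta * zz[i] - math.log(np.sum(np.exp(beta * zz[at_risk])))
    return ll


class TestCox:
    def test_toy_fit_matches_grid_search_oracle(self):
        durations, events, z = [1.0, 2.0, 3.0, 4.0], [True] * 4, [1.0, 0.0, 1.0, 0.0]
        model = cp.cox_fit(durations, events, {"group": z})
        grid = np.arange(-5.0, 5.0, 1e-4)
        lls = [cox_partial_loglik(b, durations, events, z) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert model["group"].coef == pytest.approx(best, abs=2e-3)

    def test_label_swap_inverts_hazard_ratio(self):
        rng = np.random.default_rng(3)
        z = rng.integers(0, 2, 60).astype(float)
        d = rng.exponential(10, 60) * np.where(z == 1, 0.5, 1.0)
        hr = cp.cox_fit(d, [True] * 60, {"g": z})["g"].hazard_ratio
        hr_sw = cp.cox_fit(d, [True] * 60, {"g": 1.0 - z})["g"].hazard_ratio
        assert hr_sw == pytest.approx(1.0 / hr, rel=1e-6)

    def test_recovers_true_hazard_ratio_asymptotically(self):
        """Two-arm exponential, true HR 2: estimate lands in [1.8, 2.2]."""
        rng = np.random.default_rng(11)
        n = 1000
        z = np.r_[np.zeros(n), np.ones(n)]
        d = np.r_[rng.exponential(1.0, n), rng.exponential(0.5, n)]
        model = cp.cox_fit(d, [True] * (2 * n), {"g": z})
        assert 1.8 <= model["g"].hazard_ratio <= 2.2
        assert model["g"].ci_lower < 2.0 < model["g"].ci_upper

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cp.cox_fit([1.0, 2.0], [True, True], {"g": [1.0, 1.0]})

    def test_ci_brackets_hazard_ratio(self):
        rng = np.random.default_rng(8)
        z = rng.integers(0, 2, 80).astype(float)
        d = rng.exponential(10, 80)
        eff = cp.cox_fit(d, [True] * 80, {"g": z})["g"]
        assert eff.ci_lower <= eff.hazard_ratio <= eff.ci_upper


# ---------------------------------------------------------------------------
# sleep matching


def max_matching_size(ctrl, ccm, tol):
    cids, mids = list(ctrl), list(ccm)
    rows, cols = [], []
    for i, c in enumerate(cids):
        for j, m in enumerate(mids):
            if abs(ctrl[c] - ccm[m]) <= tol:
                rows.append(i)
                cols.append(j)
    if not rows:
        return 0
    g = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(cids), len(mids))
    )
    return int((maximum_bipartite_matching(g, perm_type="column") >= 0).sum())


class TestSleepMatch:
    def test_pair_within_tolerance(self):
        ms = cp.sleep_match({"c1": 10.0}, {"m1": 10.4})
        assert ms.pairs == [("c1", "m1")]

    def test_outside_tolerance_unmatched(self):
        assert len(cp.sleep_match({"c1": 10.0}, {"m1": 10.6})) == 0

    def test_well_separated_fixture_achieves_maximum(self):
        ctrl = {"c1": 10.0, "c2": 11.0, "c3": 12.0, "c4": 20.0, "c5": 30.0}
        ccm = {"m1": 10.3, "m2": 11.2, "m3": 12.4, "m4": 19.8, "m5": 31.0}
        ms = cp.sleep_match(ctrl, ccm, 0.5)
        assert len(ms) == max_matching_size(ctrl, ccm, 0.5) == 4

    def test_no_fly_used_twice(self):
        rng = np.random.default_rng(2)
        ctrl = {f"c{i}": float(rng.normal(30, 2)) for i in range(20)}
        ccm = {f"m{i}": float(rng.normal(30, 2)) for i in range(20)}
        ms = cp.sleep_match(ctrl, ccm)
        used_c = [c for c, _ in ms.pairs]
        used_m = [m for _, m in ms.pairs]
        assert len(set(used_c)) == len(used_c)
        assert len(set(used_m)) == len(used_m)

    def test_every_pair_within_tolerance(self):
        rng = np.random.default_rng(4)
        ctrl = {f"c{i}": float(rng.normal(33, 6)) for i in range(15)}
        ccm = {f"m{i}": float(rng.normal(33, 6)) for i in range(15)}
        ms = cp.sleep_match(ctrl, ccm, 0.5)
        for c, m in ms.pairs:
            assert abs(ctrl[c] - ccm[m]) <= 0.5

    def test_deterministic(self):
        ctrl = {"c1": 10.0, "c2": 10.0}
        ccm = {"m1": 10.2, "m2": 10.2}
        assert cp.sleep_match(ctrl, ccm).pairs == cp.sleep_match(ctrl, ccm).pairs


# ---------------------------------------------------------------------------
# worked-example arithmetic


class TestPrintedStatistics:
    @pytest.mark.parametrize(
        "ctrl,ccm,expected",
        [(23.7, 20.2, 14.8), (23.0, 19.6, 14.8), (20.0, 20.0, 0.0)],
    )
    def test_percent_median_reduction(self, ctrl, ccm, expected):
        assert cp.percent_median_reduction(ctrl, ccm) == expected

    @pytest.mark.parametrize("hr,expected", [(1.94, 94), (1.0, 0), (0.74, -26)])
    def test_hazard_percent(self, hr, expected):
        assert cp.hazard_percent(hr) == expected

    @pytest.mark.parametrize(
        "hr_t,hr_s,expected", [(1.49, 0.77, 1.5), (1.0, 0.77, 0.0), (2.0, 0.5, 1.0)]
    )
    def test_equivalent_sleep_loss(self, hr_t, hr_s, expected):
        assert cp.equivalent_sleep_loss(hr_t, hr_s) == expected

    def test_non_protective_sleep_rejected(self):
        with pytest.raises(ValueError, match="protective"):
            cp.equivalent_sleep_loss(1.5, 1.1)
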