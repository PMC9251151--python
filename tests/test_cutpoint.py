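import numpy as np
import pytest

from gp96tme import cutpoint as cp


def brute_force_maxstat(values, times, events, epsilon=0.1):
    """Exhaustive independent scan: recompute the standardized log-rank
    statistic from scratch (scalar loops) at every admissible midpoint."""
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n = len(values)
    distinct = np.unique(values)
    best = (None, -1.0)
    count = 0
    for cut in (distinct[:-1] + distinct[1:]) / 2:
        prop = (values <= cut).mean()
        if not (epsilon <= prop <= 1 - epsilon):
            continue
        count += 1
        low = values <= cut
        o = e = v = 0.0
        for t in sorted(set(times[events == 1])):
            atrisk = times >= t
            y, y1 = atrisk.sum(), (atrisk & low).sum()
            d = int(((times == t) & (events == 1)).sum())
            d1 = int(((times == t) & (events == 1) & low).sum())
            o += d1
            e += d * y1 / y
            if y > 1:
                v += d * (y1 / y) * (1 - y1 / y) * (y - d) / (y - 1)
        z = abs(o - e) / np.sqrt(v) if v > 0 else 0.0
        if z > best[1] + 1e-12:
            best = (cut, z)
    return best[0], best[1], count


class TestStandardizedLogrank:
    def test_null_case_near_zero(self, rng):
        # identical survival distributions split arbitrarily
        t = rng.exponential(10, 400)
        e = np.ones(400, int)
        v = rng.normal(size=400)
        z = cp.standardized_logrank_at(v, t, e, float(np.median(v)))
        assert abs(z) < 3.0  # standardized: null z is O(1)

    def test_antisymmetry_under_label_swap(self, null_survival):
        marker, times, events = null_survival
        cut = float(np.median(marker))
        z_low = cp.standardized_logrank_at(marker, times, events, cut)
        z_high = cp.standardized_logrank_at(-marker, times, events, -cut)
        # negating the marker swaps which group is 'low' up to tie handling
        assert z_high == pytest.approx(-z_low, abs=1e-9)

    def test_six_subject_hand_oracle(self):
        # times 1..6 all events, marker ordered with survival
        times = np.arange(1.0, 7.0)
        events = np.ones(6, int)
        marker = np.arange(6.0)
        z = cp.standardized_logrank_at(marker, times, events, 2.5)
        o = e = v = 0.0
        low = marker <= 2.5
        for t in times:
            atrisk = times >= t
            y, y1 = atrisk.sum(), (atrisk & low).sum()
            d1 = int(low[int(t) - 1])
            o += d1
            e += y1 / y
            if y > 1:
                v += (y1 / y) * (1 - y1 / y)
        assert z == pytest.approx((o - e) / np.sqrt(v))

    def test_empty_group_rejected(self, null_survival):
        marker, times, events = null_survival
        with pytest.raises(ValueError, match="empty"):
            cp.standardized_logrank_at(marker, times, events, marker.max() + 1)


class TestMaxSelectedRank:
    def test_matches_brute_force_on_random_datasets(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(15, 61))
            marker = rng.normal(size=n)
            t = rng.exponential(10, n)
            c = rng.uniform(0, 30, n)
            times, events = np.minimum(t, c), (t <= c).astype(int)
            res = cp.max_selected_rank(marker, times, events)
            cut, z, count = brute_force_maxstat(marker, times, events)
            assert res.max_statistic == pytest.approx(z, abs=1e-9)
            assert res.candidate_count == count
            # selected split agrees with the oracle's split
            assert (marker <= res.cutpoint).sum() == (marker <= cut).sum()

    def test_prognostic_marker_separates_early_from_late(self, rng):
        n = 80
        marker = np.sort(rng.normal(size=n))
        times = np.sort(rng.exponential(10, n))  # marker ordered with survival
        res = cp.max_selected_rank(marker, times, np.ones(n, int))
        early = times[marker <= res.cutpoint]
        late = times[marker > res.cutpoint]
        assert np.median(early) < np.median(late)

    def test_monotone_transform_invariance(self, null_survival):
        marker, times, events = null_survival
        r1 = cp.max_selected_rank(marker, times, events)
        r2 = cp.max_selected_rank(np.exp(marker), times, events)
        assert r1.max_statistic == pytest.approx(r2.max_statistic, abs=1e-9)
        assert np.array_equal(marker <= r1.cutpoint, np.exp(marker) <= r2.cutpoint)
        assert (r1.n_low, r1.n_high) == (r2.n_low, r2.n_high)

    def test_selected_at_least_median_split(self, null_survival):
        marker, times, events = null_survival
        res = cp.max_selected_rank(marker, times, events)
        z_med = cp.standardized_logrank_at(marker, times, events,
                                           float(np.median(marker)))
        assert res.max_statistic >= abs(z_med) - 1e-12

    def test_epsilon_near_half_degenerates_to_median_split(self, null_survival):
        marker, times, events = null_survival
        res = cp.max_selected_rank(marker, times, events, epsilon=0.499)
        z_med = cp.standardized_logrank_at(marker, times, events, res.cutpoint)
        assert res.max_statistic == pytest.approx(abs(z_med))
        assert abs(res.n_low - res.n_high) <= 1

    def test_group_sizes_partition(self, null_survival):
        marker, times, events = null_survival
        res = cp.max_selected_rank(marker, times, events)
        assert res.n_low + res.n_high == marker.size


class TestPermutationPvalue:
    def test_correction_floor(self, rng):
        # strongly prognostic marker: observed max beats all 100 permutations
        n = 60
        marker = np.sort(rng.normal(size=n))
        times = np.sort(rng.exponential(10, n))
        res = cp.cutpoint_pvalue(marker, times, np.ones(n, int),
                                 n_permutations=100, seed=5)
        assert res.p_value == pytest.approx(1 / 101)

    def test_prognostic_marker_power(self):
        rng = np.random.default_rng(42)
        n = 200
        marker = rng.normal(size=n)
        lam = np.exp(np.log(4) * (marker > np.median(marker)))
        times = rng.exponential(10 / lam)
        res = cp.cutpoint_pvalue(marker, times, np.ones(n, int),
                                 n_permutations=199, seed=1)
        assert res.p_value < 0.01

    def test_deterministic_given_seed(self, null_survival):
        marker, times, events = null_survival
        p1 = cp.cutpoint_pvalue(marker, times, events, n_permutations=150, seed=9)
        p2 = cp.cutpoint_pvalue(marker, times, events, n_permutations=150, seed=9)
        assert p1.p_value == p2.p_value

    def test_too_few_permutations_rejected(self, null_survival):
        marker, times, events = null_survival
        with pytest.raises(ValueError):
            cp.cutpoint_pvalue(marker, times, events, n_permutations=50)
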