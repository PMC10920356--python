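"""Victor-Purpura metric: DP vs exhaustive edit enumeration, axioms, rank transform."""

from itertools import combinations

import numpy as np
import pytest

from spiketopo.metrics import (
    DistanceMatrix,
    distance_matrix,
    firing_rate,
    rank_order,
    select_top_active,
    vp_distance,
)
from tests.conftest import random_spike_train


def vp_bruteforce(a, b, q):
    """Minimum edit cost by enumerating every partial matching between trains.

    Unmatched spikes cost 1 each (delete/insert); a matched pair (i, j) costs
    q*|a_i - b_j|.  Exhaustive over all injective match sets, crossing ones
    included — entirely independent of the dynamic program.
    """
    n, m = len(a), len(b)
    best = n + m  # match nothing
    idx_a = range(n)
    for k in range(1, min(n, m) + 1):
        for sub_a in combinations(idx_a, k):
            for sub_b in combinations(range(m), k):
                # all bijections between the chosen subsets
                from itertools import permutations

                for perm in permutations(sub_b):
                    cost = (n - k) + (m - k) + sum(
                        q * abs(a[i] - b[j]) for i, j in zip(sub_a, perm)
                    )
                    best = min(best, cost)
    return best


class TestVPDistance:
    def test_identical_trains_zero(self):
        t = [0.1, 0.4, 0.9]
        assert vp_distance(t, t) == 0.0

    def test_empty_vs_m_spikes(self):
        assert vp_distance([], [0.1, 0.2, 0.7]) == 3.0
        assert vp_distance([0.5], []) == 1.0

    def test_single_shift_cheaper_than_delete_insert(self):
        assert vp_distance([0.10], [0.30], q=1.0) == pytest.approx(0.2)

    def test_large_q_prefers_delete_insert(self):
        assert vp_distance([0.10], [0.30], q=100.0) == pytest.approx(2.0)

    def test_q_zero_limit_is_count_distance(self, rng):
        for _ in range(20):
            a = random_spike_train(rng, rng.integers(0, 6))
            b = random_spike_train(rng, rng.integers(0, 6))
            assert vp_distance(a, b, q=0.0) == abs(len(a) - len(b))

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            vp_distance([0.5, 0.1], [0.2])

    def test_dp_equals_bruteforce_on_short_trains(self, rng):
        # exhaustive minimum over all edit matchings, >= 500 random pairs
        for _ in range(500):
            a = random_spike_train(rng, rng.integers(0, 5))
            b = random_spike_train(rng, rng.integers(0, 5))
            q = float(rng.uniform(0, 5))
            assert vp_distance(a, b, q) == pytest.approx(vp_bruteforce(a, b, q), abs=1e-12)

    def test_metric_axioms_on_random_triples(self, rng):
        trains = [random_spike_train(rng, rng.integers(1, 30)) for _ in range(60)]
        D = distance_matrix(trains, q=1.0).D
        assert np.all(np.diag(D) == 0)
        np.testing.assert_array_equal(D, D.T)
        assert np.all(D[~np.eye(len(trains), dtype=bool)] > 0)
        n = len(trains)
        count = 0
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if i != j != k:
                        assert D[i, k] <= D[i, j] + D[j, k] + 1e-12
                        count += 1
        assert count >= 1000

    def test_jitter_monotonicity(self, rng):
        # distance to a jittered copy grows with jitter magnitude (matched counts)
        from spiketopo.synthetic import jittered_copies

        base = random_spike_train(rng, 25) + 1.0  # keep jitter clear of the clip bounds
        means = []
        for sigma in [0.001, 0.01, 0.05]:
            copies = jittered_copies(base, sigma, 30, seed=int(sigma * 1e5), T=3.0)
            means.append(np.mean([vp_distance(base, c) for c in copies]))
        assert means[0] < means[1] < means[2]


class TestDistanceMatrix:
    def test_all_identical_trains_zero_matrix(self):
        t = np.array([0.2, 0.5])
        D = distance_matrix([t, t, t]).D
        assert not D.any()

    def test_consistent_with_pairwise_calls(self, rng):
        trains = [random_spike_train(rng, rng.integers(1, 8)) for _ in range(5)]
        D = distance_matrix(trains, q=2.0).D
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(vp_distance(trains[i], trains[j], 2.0))

    def test_needs_two_trains(self):
        with pytest.raises(ValueError):
            distance_matrix([np.array([0.1])])


class TestRankOrder:
    def test_hand_sorted_example(self):
        # above-diagonal distances (0.5, 0.2, 0.9) -> descending ranks (1, 2, 0)/3
        D = np.zeros((3, 3))
        D[0, 1], D[0, 2], D[1, 2] = 0.5, 0.2, 0.9
        D += D.T
        rk = rank_order(D, rates=[3.0, 2.0, 1.0])
        np.testing.assert_allclose(
            [rk.M[0, 1], rk.M[0, 2], rk.M[1, 2]], np.array([1.0, 2.0, 0.0]) / 3
        )

    def test_ascending_convention(self):
        D = np.zeros((3, 3))
        D[0, 1], D[0, 2], D[1, 2] = 0.5, 0.2, 0.9
        D += D.T
        rk = rank_order(D, rates=[3.0, 2.0, 1.0], convention="ascending")
        np.testing.assert_allclose(
            [rk.M[0, 1], rk.M[0, 2], rk.M[1, 2]], np.array([1.0, 0.0, 2.0]) / 3
        )

    def test_entries_are_normalized_rank_permutation(self, rng):
        n = 12
        D = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        D[iu] = rng.uniform(0.1, 5.0, len(iu[0]))
        D += D.T
        rk = rank_order(D, rates=rng.uniform(1, 100, n))
        K = n * (n - 1) // 2
        vals = np.sort(rk.M[np.triu_indices(n, 1)])
        np.testing.assert_allclose(vals, np.arange(K) / K)
        off_diag = rk.M[~np.eye(n, dtype=bool)]
        assert off_diag.max() <= (K - 1) / K + 1e-12

    def test_symmetry_and_rate_reindexing(self, rng):
        n = 8
        D = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        D[iu] = rng.uniform(0.1, 5.0, len(iu[0]))
        D += D.T
        rates = rng.uniform(1, 100, n)
        rk = rank_order(D, rates)
        np.testing.assert_array_equal(rk.M, rk.M.T)
        assert np.all(np.diff(rates[rk.neuron_order]) <= 0)

    def test_invariant_under_monotone_transform(self, rng):
        n = 10
        D = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        D[iu] = rng.uniform(0.1, 5.0, len(iu[0]))
        D += D.T
        rates = rng.uniform(1, 100, n)
        a = rank_order(D, rates).M
        b = rank_order(np.sqrt(D) + 2 * D, rates).M  # strictly monotone transform
        np.testing.assert_array_equal(a, b)

    def test_order_reversal_between_D_and_M(self, rng):
        n = 7
        D = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        D[iu] = rng.uniform(0.1, 5.0, len(iu[0]))
        D += D.T
        rates = np.arange(n, 0, -1.0)  # identity permutation
        M = rank_order(D, rates).M
        for (i, j), (k, l) in combinations(list(zip(*iu)), 2):
            if D[i, j] < D[k, l]:
                assert M[i, j] > M[k, l]

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            rank_order(D, [1.0, 2.0, 3.0])


class TestRatesAndSelection:
    def test_firing_rate(self):
        assert firing_rate(np.linspace(0.01, 0.99, 50), 1.0) == 50.0
        assert firing_rate([], 2.0) == 0.0

    def test_firing_rate_consistent_with_trace_average(self, rng):
        from spiketopo.network import SpikeRaster, mean_rate_trace

        trains = [random_spike_train(rng, rng.integers(10, 80)) for _ in range(30)]
        raster = SpikeRaster(trains=trains, duration=1.0)
        _, trace = mean_rate_trace(raster, 0.02)
        per_neuron = np.mean([firing_rate(t, 1.0) for t in trains])
        assert trace.mean() == pytest.approx(per_neuron, rel=0.02)

    def test_top_k_selection(self, rng):
        rates = rng.permutation(50).astype(float)
        top = select_top_active(rates, 10)
        assert set(top) == set(np.argsort(rates)[::-1][:10])
        assert select_top_active(rates, 1)[0] == np.argmax(rates)
        assert set(select_top_active(rates, 50)) == set(range(50))

    def test_rate_ties_prefer_lower_index(self):
        assert list(select_top_active([5.0, 5.0, 1.0], 1)) == [0]
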