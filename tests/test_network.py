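"""LIF reservoir: connectivity statistics, single-neuron dynamics, raster invariants."""

import numpy as np
import pytest

import spiketopo.network as net
from spiketopo.network import (
    Connectivity,
    NetworkState,
    NeuronParams,
    SpikeRaster,
    effective_coupling,
    init_connectivity,
    mean_rate_trace,
    readout,
    run,
    step,
)


@pytest.fixture
def params():
    return NeuronParams(I_bias=0.0)


def suprathreshold(I):
    return NeuronParams(I_bias=I)


class TestConnectivity:
    def test_seed_determinism(self):
        a = init_connectivity(50, 2, p=0.2, g=1.5, q_fb=2.0, seed=7)
        b = init_connectivity(50, 2, p=0.2, g=1.5, q_fb=2.0, seed=7)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.U, b.U)

    def test_weight_standard_deviation(self):
        conn = init_connectivity(2000, 2, p=1.0, g=1.0, seed=0)
        assert conn.A.std() == pytest.approx(2000**-0.5, rel=0.02)

    def test_sparsity_fraction(self):
        conn = init_connectivity(500, 2, p=0.1, g=1.0, seed=1)
        frac = np.count_nonzero(conn.A) / conn.A.size
        assert frac == pytest.approx(0.1, abs=0.01)

    def test_zero_feedback_gives_zero_U(self):
        conn = init_connectivity(20, 2, p=0.5, g=1.0, q_fb=0.0, seed=0)
        assert not conn.U.any()

    def test_readout_starts_at_zero(self):
        conn = init_connectivity(20, 3, p=0.5, g=1.0, seed=0)
        assert not conn.W.any()

    def test_impossible_sparsity_rejected(self):
        with pytest.raises(ValueError):
            init_connectivity(5, 2, p=0.1, g=1.0, seed=0)


class TestEffectiveCoupling:
    def test_untrained_equals_A(self):
        conn = init_connectivity(30, 2, p=0.5, g=1.0, seed=0)
        np.testing.assert_array_equal(effective_coupling(conn), conn.A)

    def test_low_rank_perturbation(self, rng):
        conn = init_connectivity(30, 2, p=0.5, g=1.0, seed=0)
        conn.W = rng.normal(size=conn.W.shape)
        omega = effective_coupling(conn)
        assert np.linalg.matrix_rank(omega - conn.A) <= conn.n_outputs

    def test_matches_triple_loop(self, rng):
        N, M = 6, 2
        conn = init_connectivity(N, M, p=1.0, g=1.0, seed=3)
        conn.W = rng.normal(size=(M, N))
        expected = np.zeros((N, N))
        for i in range(N):
            for j in range(N):
                expected[i, j] = conn.A[i, j] + sum(
                    conn.U[i, k] * conn.W[k, j] for k in range(M)
                )
        np.testing.assert_allclose(effective_coupling(conn), expected, atol=1e-12)


def _single_neuron_conn():
    return Connectivity(
        A=np.zeros((1, 1)), U=np.zeros((1, 2)), W=np.zeros((2, 1)),
        sparsity=1.0, gain=0.0, feedback_strength=0.0,
    )


class TestSingleNeuron:
    def test_resting_fixed_point(self, params):
        conn = _single_neuron_conn()
        state = NetworkState(
            v=np.array([params.v_rest]), r=np.zeros(1), h=np.zeros(1),
            refractory_remaining=np.zeros(1),
        )
        for _ in range(200):
            state, spiked = step(state, conn, params, 1e-4)
            assert spiked.size == 0
        assert state.v[0] == pytest.approx(params.v_rest)

    def test_interspike_interval_matches_closed_form(self):
        # constant suprathreshold drive: ISI = tau_ref + tau_m ln((v_inf-v_reset)/(v_inf-v_th))
        I = 30.0
        params = suprathreshold(I)
        dt = 5e-5
        conn = _single_neuron_conn()
        raster, _, _, _ = run(conn, params, 1.0, dt, seed=0)
        isis = np.diff(raster.trains[0])
        v_inf = params.v_rest + I
        expected_ms = params.tau_refractory + params.tau_m * np.log(
            (v_inf - params.v_reset) / (v_inf - params.v_th)
        )
        assert np.allclose(isis, expected_ms * 1e-3, atol=2 * dt)

    def test_synaptic_filter_shape_and_area(self, params):
        # inject one spike into the (r, h) pair and follow the filter analytically
        dt = 5e-5
        tr, td = params.tau_rise * 1e-3, params.tau_decay * 1e-3
        er, ed, c = net._synapse_propagators(params, dt)
        h = net._h_kick(params)
        r = 0.0
        ts, rs = [], []
        for k in range(int(0.3 / dt)):
            r = ed * r + c * h
            h = er * h
            ts.append((k + 1) * dt)
            rs.append(r)
        ts, rs = np.asarray(ts), np.asarray(rs)
        analytic = (np.exp(-ts / td) - np.exp(-ts / tr)) / (td - tr)
        np.testing.assert_allclose(rs, analytic, rtol=1e-6, atol=1e-9)
        assert abs(np.sum(rs) * dt - 1.0) < 1e-3  # unit area
        # peak at t* = ln(td/tr) * tr*td/(td-tr)
        t_peak = np.log(td / tr) * tr * td / (td - tr)
        assert ts[np.argmax(rs)] == pytest.approx(t_peak, abs=2 * dt)


class TestRun:
    def test_zero_coupling_zero_bias_silent(self, params):
        conn = init_connectivity(10, 2, p=1.0, g=0.0, q_fb=0.0, seed=0)
        raster, _, z, _ = run(conn, params, 0.2, 1e-4, seed=1)
        assert raster.n_spikes == 0
        assert not z.any()

    def test_raster_respects_refractoriness(self):
        params = suprathreshold(35.0)
        conn = init_connectivity(20, 2, p=0.5, g=0.5, q_fb=0.0, seed=2)
        raster, _, _, _ = run(conn, params, 0.5, 5e-5, seed=3)
        assert raster.n_spikes > 0
        for train in raster.trains:
            if len(train) > 1:
                assert np.diff(train).min() >= params.tau_refractory * 1e-3 - 1e-12

    def test_seed_determinism(self):
        params = suprathreshold(30.0)
        conn = init_connectivity(15, 2, p=0.5, g=0.5, q_fb=0.0, seed=2)
        r1, _, z1, _ = run(conn, params, 0.2, 1e-4, seed=5)
        r2, _, z2, _ = run(conn, params, 0.2, 1e-4, seed=5)
        np.testing.assert_array_equal(z1, z2)
        for a, b in zip(r1.trains, r2.trains):
            np.testing.assert_array_equal(a, b)

    def test_step_and_run_agree(self):
        # the optimized run loop must reproduce repeated step() calls exactly
        params = suprathreshold(30.0)
        conn = init_connectivity(12, 2, p=0.5, g=0.4, q_fb=1.0, seed=4)
        conn.W = np.random.default_rng(0).normal(0, 0.01, size=conn.W.shape)
        dt = 1e-4
        state = net.initial_state(conn, params, seed=9)
        spikes = [[] for _ in range(12)]
        s = state.copy()
        for k in range(2000):
            s, fired = step(s, conn, params, dt)
            for i in fired:
                spikes[i].append(s.t)
        raster, _, _, final = run(conn, params, 0.2, dt, seed=9)
        for a, b in zip(spikes, raster.trains):
            np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_allclose(final.v, s.v, atol=1e-9)

    def test_dt_self_convergence(self):
        # halving dt changes spike times only by O(dt) on a small network
        params = suprathreshold(30.0)
        conn = init_connectivity(10, 2, p=1.0, g=0.05, q_fb=0.0, seed=6)
        fine, _, _, _ = run(conn, params, 0.2, 2.5e-5, seed=7)
        coarse, _, _, _ = run(conn, params, 0.2, 5e-5, seed=7)
        for a, b in zip(fine.trains, coarse.trains):
            n = min(len(a), len(b))
            assert n > 0
            assert np.max(np.abs(a[:n] - b[:n])) < 2e-3


class TestMeanRateTrace:
    def test_uniform_raster_gives_flat_trace(self):
        trains = [np.linspace(0.01, 0.99, 50)] * 10
        raster = SpikeRaster(trains=trains, duration=1.0)
        _, rate = mean_rate_trace(raster, 0.02)
        assert rate.mean() == pytest.approx(50.0, rel=0.02)
        assert rate.std() < 5.0

    def test_empty_raster_is_zero(self):
        raster = SpikeRaster(trains=[np.empty(0)] * 5, duration=1.0)
        _, rate = mean_rate_trace(raster, 0.02)
        assert not rate.any()

    def test_tracks_inhomogeneous_poisson_profile(self, rng):
        # lambda(t) = 40 + 30 sin(2 pi t): the windowed trace follows it
        T, n = 1.0, 200
        grid = np.linspace(0, T, 1001)
        lam = 40 + 30 * np.sin(2 * np.pi * grid)
        trains = []
        for _ in range(n):
            cand = np.sort(rng.uniform(0, T, rng.poisson(70 * T)))
            keep = rng.uniform(0, 70, len(cand)) < np.interp(cand, grid, lam)
            trains.append(cand[keep])
        t, rate = mean_rate_trace(SpikeRaster(trains=trains, duration=T), 0.02)
        expected = 40 + 30 * np.sin(2 * np.pi * t)
        assert np.max(np.abs(rate - expected)) < 15.0  # sampling error bound

    def test_readout_linear_in_rates(self, rng):
        conn = init_connectivity(8, 2, p=1.0, g=0.1, seed=0)
        conn.W = rng.normal(size=conn.W.shape)
        state = net.initial_state(conn, NeuronParams(), seed=1)
        state.r = rng.uniform(0, 50, size=8)
        expected = np.array(
            [sum(conn.W[k, i] * state.r[i] for i in range(8)) for k in range(2)]
        )
        np.testing.assert_allclose(readout(conn, state), expected, atol=1e-12)
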