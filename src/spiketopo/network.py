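"""Recurrent leaky integrate-and-fire (LIF) reservoir with double-exponential synapses.

Model
-----
Each of N neurons carries a membrane potential v_i obeying

    tau_m dv_i/dt = v_rest - v_i + I_bias + sum_j omega_ij r_j ,

where omega = A + U W^T combines the fixed sparse recurrent weights A, the
fixed random feedback weights U (N x M) and the trainable linear readout
W (M x N).  When v_i crosses v_th the neuron spikes, v_i resets to v_reset and
is clamped there for an absolute refractory period.  Spikes are filtered by a
double-exponential synapse

    dr_i/dt = -r_i/tau_d + h_i ,
    dh_i/dt = -h_i/tau_r + (1/(tau_r tau_d)) sum_k delta(t - t_k^(i)) ,

whose single-spike response (exp(-t/tau_d) - exp(-t/tau_r)) / (tau_d - tau_r)
has unit time-integral, so the stationary r_i approximates the firing rate in
spikes/s.  The readout is z_hat = W r and is fed back through U, closing the
autonomous loop.

Integration is forward Euler for v with exact exponential integration of the
(r, h) pair within each step; spike times are recorded at the end of the step
in which threshold is crossed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "NeuronParams",
    "Connectivity",
    "NetworkState",
    "SpikeRaster",
    "init_connectivity",
    "effective_coupling",
    "step",
    "readout",
    "run",
    "mean_rate_trace",
    "count_rate_excursions",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF single-neuron and synapse parameters.

    Time constants are in milliseconds, voltages in mV.  ``tau_refractory`` is
    the absolute refractory period (a distinct parameter from the synaptic
    rise constant ``tau_rise``).  ``I_bias`` is a constant current expressed
    in voltage units; the effective resting level is v_rest + I_bias.
    """

    tau_m: float = 10.0
    v_rest: float = -65.0
    v_th: float = -40.0
    v_reset: float = -65.0
    tau_refractory: float = 2.0
    tau_rise: float = 2.0
    tau_decay: float = 20.0
    I_bias: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_rise", "tau_decay", "tau_refractory"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_rise == self.tau_decay:
            raise ValueError("tau_rise must differ from tau_decay")
        if self.v_reset > self.v_th:
            raise ValueError("require v_reset <= v_th")
        if self.v_rest >= self.v_th:
            raise ValueError("require v_rest < v_th")


@dataclass
class Connectivity:
    """Weight matrices of the reservoir.

    A : (N, N) fixed sparse recurrent weights (dense ndarray)
    U : (N, M) fixed feedback weights, uniform in [-q_fb, q_fb]
    W : (M, N) trainable readout weights (zero before training)
    """

    A: np.ndarray
    U: np.ndarray
    W: np.ndarray
    sparsity: float
    gain: float
    feedback_strength: float

    @property
    def n_neurons(self) -> int:
        return self.A.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.U.shape[1]


@dataclass
class NetworkState:
    """Instantaneous dynamical state of the network."""

    v: np.ndarray
    r: np.ndarray
    h: np.ndarray
    refractory_remaining: np.ndarray  # ms
    t: float = 0.0  # s

    def copy(self) -> "NetworkState":
        return NetworkState(
            v=self.v.copy(),
            r=self.r.copy(),
            h=self.h.copy(),
            refractory_remaining=self.refractory_remaining.copy(),
            t=self.t,
        )


@dataclass
class SpikeRaster:
    """Per-neuron sorted spike times (seconds) over a trial of length duration."""

    trains: list
    duration: float

    def __post_init__(self) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.trains))

    def rates(self) -> np.ndarray:
        """Per-neuron mean firing rate in Hz (count / duration)."""
        return np.array([len(t) / self.duration for t in self.trains])


def init_connectivity(
    N: int,
    M: int = 2,
    *,
    p: float = 0.1,
    g: float = 1.0,
    q_fb: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> Connectivity:
    """Draw the fixed weights of a reservoir.

    Nonzero entries of A are Gaussian with zero mean and standard deviation
    g / sqrt(p N); each entry is independently nonzero with probability p
    (self-connections included).  U is uniform in [-q_fb, q_fb]; W starts at
    zero.
    """
    if N <= 0 or M < 1:
        raise ValueError("require N > 0 and M >= 1")
    if not 0 < p <= 1:
        raise ValueError("require 0 < p <= 1")
    if p * N < 1:
        raise ValueError(f"p*N = {p * N:.3g} < 1: no connections possible")
    rng = np.random.default_rng(seed)
    mask = rng.random((N, N)) < p
    A = np.where(mask, rng.normal(0.0, g / np.sqrt(p * N), size=(N, N)), 0.0)
    U = rng.uniform(-q_fb, q_fb, size=(N, M)) if q_fb > 0 else np.zeros((N, M))
    W = np.zeros((M, N))
    return Connectivity(A=A, U=U, W=W, sparsity=p, gain=g, feedback_strength=q_fb)


def effective_coupling(conn: Connectivity) -> np.ndarray:
    """Effective recurrent topology Omega = A + U @ W (Omega_ij = a_ij + sum_k u_ik w_kj)."""
    if conn.U.shape != (conn.A.shape[0], conn.W.shape[0]) or conn.W.shape[1] != conn.A.shape[1]:
        raise ValueError("inconsistent shapes among A, U, W")
    return conn.A + conn.U @ conn.W


def readout(conn: Connectivity, state: NetworkState) -> np.ndarray:
    """Linear readout z_hat_k = sum_i w_ki r_i."""
    return conn.W @ state.r


def initial_state(
    conn: Connectivity, params: NeuronParams, seed: int | np.random.Generator = 0
) -> NetworkState:
    """Voltages uniform in [v_reset, v_th]; synapses at rest."""
    rng = np.random.default_rng(seed)
    N = conn.n_neurons
    v0 = rng.uniform(params.v_reset, params.v_th, size=N)
    return NetworkState(
        v=v0, r=np.zeros(N), h=np.zeros(N), refractory_remaining=np.zeros(N), t=0.0
    )


def _synapse_propagators(params: NeuronParams, dt: float):
    """Exact one-step propagator of the linear (r, h) pair over dt seconds.

    r(t+dt) = ed * r + c * h,  h(t+dt) = er * h, with
    c = (tau_r tau_d / (tau_r - tau_d)) (er - ed).  Time constants are
    converted to seconds so r carries units of s^-1 (a unit-area spike
    response), making the stationary r_i comparable to the rate in Hz.
    """
    tr = params.tau_rise * 1e-3
    td = params.tau_decay * 1e-3
    er = np.exp(-dt / tr)
    ed = np.exp(-dt / td)
    c = tr * td / (tr - td) * (er - ed)
    return er, ed, c


def _h_kick(params: NeuronParams) -> float:
    """Per-spike increment of h: 1/(tau_rise * tau_decay) in s^-2."""
    return 1.0 / (params.tau_rise * 1e-3 * params.tau_decay * 1e-3)


def step(
    state: NetworkState,
    conn: Connectivity,
    params: NeuronParams,
    dt: float,
    *,
    feedback: np.ndarray | None = None,
    omega=None,
) -> tuple[NetworkState, np.ndarray]:
    """Advance the network by one time step of dt seconds.

    By default the feedback carries the network's own readout (autonomous
    operation); pass ``feedback`` to drive the loop with an external signal
    instead.  ``omega`` may supply a precomputed coupling operator (dense or
    scipy.sparse) for A; when omitted the drive is computed as
    A @ r + U @ (W @ r), which equals Omega @ r.

    Returns the new state and the array of neuron ids that spiked this step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.all(np.isfinite(state.v)) and np.all(np.isfinite(state.r))):
        raise FloatingPointError(
            "non-finite network state: integration unstable, try a smaller dt"
        )
    dt_ms = dt * 1e3
    new = state.copy()
    z = conn.W @ state.r if feedback is None else np.asarray(feedback, dtype=float)
    A_op = conn.A if omega is None else omega
    drive = A_op @ state.r + conn.U @ z

    refractory = state.refractory_remaining > 0
    dv = (params.v_rest - state.v + params.I_bias + drive) * (dt_ms / params.tau_m)
    new.v = np.where(refractory, params.v_reset, state.v + dv)
    new.refractory_remaining = np.maximum(state.refractory_remaining - dt_ms, 0.0)

    spiked = np.flatnonzero(new.v >= params.v_th)
    if spiked.size:
        new.v[spiked] = params.v_reset
        new.refractory_remaining[spiked] = params.tau_refractory

    er, ed, c = _synapse_propagators(params, dt)
    new.r = ed * state.r + c * state.h
    new.h = er * state.h
    if spiked.size:
        new.h[spiked] += _h_kick(params)

    new.t = state.t + dt
    return new, spiked


def _as_operator(A: np.ndarray, sparsity: float):
    """CSR view of A when sparse enough to pay off."""
    if sparsity <= 0.3:
        return sp.csr_matrix(A)
    return A


def run(
    conn: Connectivity,
    params: NeuronParams,
    duration: float,
    dt: float = 5e-5,
    *,
    seed: int | np.random.Generator = 0,
    state: NetworkState | None = None,
    record_every: int = 20,
) -> tuple[SpikeRaster, np.ndarray, np.ndarray, NetworkState]:
    """Simulate the autonomous network (feedback = its own readout).

    Returns (raster, times, z_hat trace of shape (n_rec, M), final state).
    ``record_every`` subsamples the stored readout trace (the simulation step
    is always dt).  Pass ``state`` to continue from a previous run.
    """
    N = conn.n_neurons
    if state is None:
        state = initial_state(conn, params, seed)
    n_steps = int(round(duration / dt))
    dt_ms = dt * 1e3
    er, ed, c = _synapse_propagators(params, dt)
    h_kick = _h_kick(params)
    A_op = _as_operator(conn.A, conn.sparsity)
    U, W = conn.U, conn.W

    v = state.v.copy()
    r = state.r.copy()
    h = state.h.copy()
    refrac = state.refractory_remaining.copy()
    t0 = state.t

    spike_times: list[list[float]] = [[] for _ in range(N)]
    rec_t, rec_z = [], []
    leak = dt_ms / params.tau_m
    base = params.v_rest + params.I_bias

    for k in range(n_steps):
        z = W @ r
        drive = A_op @ r + U @ z
        in_refrac = refrac > 0.0
        v += leak * (base - v + drive)
        v[in_refrac] = params.v_reset
        np.subtract(refrac, dt_ms, out=refrac)
        np.maximum(refrac, 0.0, out=refrac)

        spiked = np.flatnonzero(v >= params.v_th)
        r *= ed
        r += c * h
        h *= er
        t_now = t0 + (k + 1) * dt
        if spiked.size:
            v[spiked] = params.v_reset
            refrac[spiked] = params.tau_refractory
            h[spiked] += h_kick
            for i in spiked:
                spike_times[i].append(t_now)
        if k % record_every == 0:
            if not np.isfinite(v[0]):
                raise FloatingPointError("non-finite state during run; reduce dt or gain")
            rec_t.append(t_now)
            rec_z.append(W @ r)

    raster = SpikeRaster(
        trains=[np.asarray(ts) - t0 for ts in spike_times], duration=duration
    )
    final = NetworkState(v=v, r=r, h=h, refractory_remaining=refrac, t=t0 + n_steps * dt)
    return raster, np.asarray(rec_t) - t0, np.asarray(rec_z), final


def mean_rate_trace(
    raster: SpikeRaster,
    window: float = 0.02,
    *,
    bin_width: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Population firing rate (Hz per neuron) in a sliding window.

    Spikes of all neurons are binned at ``bin_width`` and averaged over a
    sliding window of length ``window``; edge windows are normalized by their
    actual overlap with the trial so a uniform raster gives a flat trace.

    Returns (bin centers, rate trace).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    T = raster.duration
    n_bins = max(int(round(T / bin_width)), 1)
    edges = np.linspace(0.0, T, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    all_spikes = (
        np.concatenate([t for t in raster.trains if len(t)])
        if raster.n_spikes
        else np.empty(0)
    )
    counts, _ = np.histogram(all_spikes, bins=edges)
    w = max(int(round(window / bin_width)), 1)
    kernel = np.ones(w)
    smoothed = np.convolve(counts, kernel, mode="same")
    coverage = np.convolve(np.ones(n_bins), kernel, mode="same")  # bins actually inside
    rate = smoothed / (coverage * bin_width * max(raster.n_neurons, 1))
    return centers, rate


def count_rate_excursions(
    rate: np.ndarray,
    *,
    smooth_bins: int = 31,
    prominence_frac: float = 0.3,
    min_separation_frac: float = 1 / 6.0,
) -> int:
    """Number of rise-fall excursions of a periodic rate trace.

    The trace is treated as one full period (circular), smoothed with a
    moving average, and peaks are counted with a prominence threshold
    relative to the trace's span; a petal straddling the trial boundary is
    counted once.
    """
    from scipy.signal import find_peaks

    rate = np.asarray(rate, dtype=float)
    n = len(rate)
    sm = np.convolve(rate, np.ones(smooth_bins) / smooth_bins, mode="same")
    span = sm.max() - sm.min()
    if span == 0:
        return 0
    ext = np.concatenate([sm, sm, sm])
    peaks, _ = find_peaks(
        ext, prominence=span * prominence_frac, distance=max(int(n * min_separation_frac), 1)
    )
    return int(np.sum((peaks >= n) & (peaks < 2 * n)))
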