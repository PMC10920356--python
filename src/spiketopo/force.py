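"""FORCE training of the readout by recursive least squares (RLS).

The readout matrix W (M x N) is the only trained object.  Every update
interval Delta_t the error between readout and teacher,

    e(t) = z_hat(t) - z(t) = W r(t) - z(t),

drives the RLS update

    P <- P - (P r r^T P) / (1 + r^T P r),        P(0) = I / alpha,
    W <- W - (P r e^T)^T = W - e (P r)^T,

where P is a running estimate of the regularized inverse correlation matrix
of the filtered rates.  After k updates with rate vectors r_1..r_k, P equals
(alpha I + sum_j r_j r_j^T)^{-1} exactly (up to round-off) — this closed form
is the correctness surface the tests lean on.

During training the feedback loop carries the network's own readout z_hat
(classic FORCE; since W is corrected every few ms, z_hat shadows the teacher
almost immediately).  Full teacher forcing is available via
``teacher_forcing=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network import (
    Connectivity,
    NetworkState,
    NeuronParams,
    SpikeRaster,
    _as_operator,
    _h_kick,
    _synapse_propagators,
    initial_state,
)
from .targets import TargetSpec, Trajectory, evaluate_target

__all__ = ["RLSState", "TrainConfig", "compute_error", "rls_update", "weight_update", "train"]


@dataclass
class RLSState:
    """Running inverse-correlation estimate P (N x N, symmetric PD)."""

    P: np.ndarray
    alpha: float
    update_interval: float  # seconds

    @classmethod
    def initialize(cls, N: int, alpha: float, update_interval: float) -> "RLSState":
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        return cls(P=np.eye(N) / alpha, alpha=alpha, update_interval=update_interval)


@dataclass(frozen=True)
class TrainConfig:
    """Schedule and hyperparameters of a FORCE run.

    total_training_time : s of simulated time with RLS active
    update_interval     : s between RLS/weight updates (must exceed the
                          simulator dt)
    alpha               : RLS regularizer; P(0) = I/alpha
    settle_time         : s of free running before updates start
    dw_tolerance        : early stop when the per-interval Frobenius norm of
                          the weight change stays below this for
                          ``patience`` consecutive intervals (0 disables)
    teacher_forcing     : feed the teacher z(t) instead of z_hat(t) through
                          the feedback during training
    """

    total_training_time: float = 6.0
    update_interval: float = 2e-3
    alpha: float = 0.05
    settle_time: float = 0.2
    dw_tolerance: float = 0.0
    patience: int = 50
    teacher_forcing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def compute_error(W: np.ndarray, r: np.ndarray, z_target: np.ndarray) -> np.ndarray:
    """Readout error e = W r - z (shape (M,))."""
    W = np.asarray(W, dtype=float)
    r = np.asarray(r, dtype=float)
    z = np.asarray(z_target, dtype=float)
    if W.shape[1] != r.shape[0] or W.shape[0] != z.shape[0]:
        raise ValueError("shape mismatch among W, r, z_target")
    return W @ r - z


def rls_update(rls: RLSState, r: np.ndarray) -> RLSState:
    """Sherman–Morrison downdate of P for one rate sample r (in place on a copy).

    Symmetry is re-enforced as (P + P^T)/2 to keep P positive definite over
    long update sequences.
    """
    P = rls.P
    if not np.all(np.isfinite(P)):
        raise FloatingPointError("non-finite P in RLS state")
    r = np.asarray(r, dtype=float)
    Pr = P @ r
    denom = 1.0 + float(r @ Pr)
    P_new = P - np.outer(Pr, Pr) / denom
    P_new = 0.5 * (P_new + P_new.T)
    return RLSState(P=P_new, alpha=rls.alpha, update_interval=rls.update_interval)


def weight_update(W: np.ndarray, rls: RLSState, r: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Apply W <- W - e (P r)^T with the already-updated P.

    ``e`` must be computed with the pre-update W at the same instant.
    """
    W = np.asarray(W, dtype=float)
    r = np.asarray(r, dtype=float)
    e = np.asarray(e, dtype=float)
    if W.shape != (e.shape[0], r.shape[0]):
        raise ValueError("shape mismatch among W, r, e")
    return W - np.outer(e, rls.P @ r)


def train(
    conn: Connectivity,
    params: NeuronParams,
    target: TargetSpec | Trajectory,
    cfg: TrainConfig,
    dt: float = 5e-5,
    *,
    state: NetworkState | None = None,
) -> tuple[Connectivity, np.ndarray, NetworkState]:
    """FORCE-train the readout of ``conn`` on a periodic planar target.

    The target may be a TargetSpec (evaluated analytically, wrapped modulo its
    period) or a pre-sampled Trajectory (zero-order hold at simulator steps).
    The network first free-runs for ``cfg.settle_time``; RLS then updates W
    every ``cfg.update_interval`` for ``cfg.total_training_time`` seconds of
    simulated time.

    Returns (connectivity with trained W, error history array of shape
    (n_intervals, 2) with columns (t, rmse), final network state).  The final
    state allows evaluation to continue phase-aligned with the teacher clock.
    """
    if cfg.update_interval <= dt:
        raise ValueError("update_interval must exceed the simulator dt")
    N = conn.n_neurons
    M = conn.n_outputs
    rng = np.random.default_rng(cfg.seed)
    if state is None:
        state = initial_state(conn, params, rng)

    if isinstance(target, Trajectory):
        period = float(target.times[-1])
        ttimes = target.times

        def teacher(t: float) -> np.ndarray:
            idx = min(int((t % period) / (ttimes[1] - ttimes[0])), len(ttimes) - 1)
            return np.array([target.x[idx], target.y[idx]])

    else:

        def teacher(t: float) -> np.ndarray:
            x, y = evaluate_target(target, np.array([t]))
            return np.array([x[0], y[0]])

    dt_ms = dt * 1e3
    er, ed, c = _synapse_propagators(params, dt)
    h_kick = _h_kick(params)
    A_op = _as_operator(conn.A, conn.sparsity)
    U = conn.U
    W = conn.W.copy()
    leak = dt_ms / params.tau_m
    base = params.v_rest + params.I_bias

    v = state.v.copy()
    r = state.r.copy()
    h = state.h.copy()
    refrac = state.refractory_remaining.copy()
    t = state.t

    P = np.eye(N) / cfg.alpha
    steps_per_update = max(int(round(cfg.update_interval / dt)), 1)
    n_settle = int(round(cfg.settle_time / dt))
    n_train = int(round(cfg.total_training_time / dt))
    history = []
    quiet = 0

    for k in range(n_settle + n_train):
        z_hat = W @ r
        z_fb = teacher(t) if cfg.teacher_forcing else z_hat
        drive = A_op @ r + U @ z_fb
        in_refrac = refrac > 0.0
        v += leak * (base - v + drive)
        v[in_refrac] = params.v_reset
        np.subtract(refrac, dt_ms, out=refrac)
        np.maximum(refrac, 0.0, out=refrac)
        spiked = np.flatnonzero(v >= params.v_th)
        r *= ed
        r += c * h
        h *= er
        if spiked.size:
            v[spiked] = params.v_reset
            refrac[spiked] = params.tau_refractory
            h[spiked] += h_kick
        t += dt

        training = k >= n_settle
        if training and (k - n_settle) % steps_per_update == 0:
            z = teacher(t)
            e = W @ r - z
            rmse = float(np.sqrt(np.mean(e**2)))
            if not np.isfinite(rmse) or rmse > 1e6:
                raise FloatingPointError(
                    "FORCE training diverged (unbounded error); "
                    "recalibrate the coupling gain g or the RLS alpha"
                )
            Pr = P @ r
            denom = 1.0 + float(r @ Pr)
            P -= np.outer(Pr, Pr / denom)
            P = 0.5 * (P + P.T)
            dW = np.outer(e, P @ r)
            W -= dW
            history.append((t - state.t, rmse))
            if cfg.dw_tolerance > 0:
                quiet = quiet + 1 if np.linalg.norm(dW) < cfg.dw_tolerance else 0
                if quiet >= cfg.patience:
                    break

    trained = Connectivity(
        A=conn.A,
        U=conn.U,
        W=W,
        sparsity=conn.sparsity,
        gain=conn.gain,
        feedback_strength=conn.feedback_strength,
    )
    final = NetworkState(v=v, r=r, h=h, refractory_remaining=refrac, t=t)
    return trained, np.asarray(history), final
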