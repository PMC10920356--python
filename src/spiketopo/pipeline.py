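"""End-to-end orchestration: train -> generate -> VP metrics -> persistence.

``run_full`` performs the whole study for one target: FORCE-train the
readout, freeze W, let the network draw autonomously for one trial (1 s, one
closed traversal), collect the spike raster, compute the VP distance matrix
D, the normalized rank-ordered matrix M, restrict to the top-k most active
neurons, and compute the persistence barcode and Betti curves.  Every stage
writes its artifact to ``output_dir`` and the run finishes with a JSON
manifest of paths, SHA-256 checksums and wall-clock timings.

``run_analysis_only`` applies the metric/topology stages to any stored or
user-supplied raster; ``run_trajectory_eval`` measures how well a trained
archive reproduces its target.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, asdict
from math import inf
from pathlib import Path

import numpy as np

from . import io
from .calibrate import bias_for_rate
from .force import TrainConfig, train
from .metrics import RankMatrix, distance_matrix, rank_order, select_top_active
from .network import Connectivity, NeuronParams, SpikeRaster, init_connectivity, mean_rate_trace, run
from .targets import TargetSpec, evaluate_target, generate_target
from .topology import betti_curve, default_grid, rips_persistence

__all__ = [
    "AnalysisConfig",
    "PipelineConfig",
    "RunManifest",
    "run_full",
    "run_analysis_only",
    "run_trajectory_eval",
    "default_neuron_params",
]

#: calibrated defaults of the drawing experiments (see docs/methods.md):
#: uncoupled tonic rate centered on the printed circle band, modest gain.
DEFAULT_TONIC_RATE = 38.0  # Hz
DEFAULT_GAIN = 0.08
DEFAULT_FEEDBACK = 90.0
DEFAULT_SPARSITY = 0.1


def default_neuron_params(tonic_rate: float = DEFAULT_TONIC_RATE) -> NeuronParams:
    """LIF defaults with the bias calibrated to a tonic uncoupled rate (Hz)."""
    base = NeuronParams()
    return NeuronParams(
        tau_m=base.tau_m,
        v_rest=base.v_rest,
        v_th=base.v_th,
        v_reset=base.v_reset,
        tau_refractory=base.tau_refractory,
        tau_rise=base.tau_rise,
        tau_decay=base.tau_decay,
        I_bias=bias_for_rate(base, tonic_rate),
    )


@dataclass(frozen=True)
class AnalysisConfig:
    """Metric/topology stage parameters."""

    q: float = 1.0  # VP shift cost, s^-1
    top_k: int = 100
    rank_convention: str = "descending"
    betti_grid: int = 512


@dataclass
class PipelineConfig:
    """Full-study configuration (JSON-serializable)."""

    target: TargetSpec = field(default_factory=lambda: TargetSpec("circle"))
    n_neurons: int = 1000
    n_outputs: int = 2
    sparsity: float = DEFAULT_SPARSITY
    gain: float = DEFAULT_GAIN
    feedback_strength: float = DEFAULT_FEEDBACK
    tonic_rate: float = DEFAULT_TONIC_RATE
    neuron: NeuronParams | None = None
    training: TrainConfig = field(default_factory=TrainConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    dt: float = 5e-5
    seed_connectivity: int = 1
    seed_training: int = 2
    seed_simulation: int = 3
    output_dir: str = "results/run"

    def neuron_params(self) -> NeuronParams:
        return self.neuron if self.neuron is not None else default_neuron_params(self.tonic_rate)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["neuron"] = None if self.neuron is None else asdict(self.neuron)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["target"] = TargetSpec(**d["target"])
        if d.get("neuron"):
            d["neuron"] = NeuronParams(**d["neuron"])
        d["training"] = TrainConfig(**d["training"])
        d["analysis"] = AnalysisConfig(**d["analysis"])
        return cls(**d)


@dataclass
class RunManifest:
    """Record of a pipeline run: config snapshot, artifacts, checksums, timings."""

    config: dict
    files: dict
    checksums: dict
    timings: dict
    summary: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _analyze(
    raster: SpikeRaster, cfg: AnalysisConfig, outdir: Path, files: dict, timings: dict
) -> dict:
    """Shared metric/topology tail: D -> M -> top-k -> persistence -> Betti."""
    if raster.n_neurons < 2:
        raise ValueError("need at least 2 spike trains for the metric stage")
    if not 1 <= cfg.top_k:
        raise ValueError("top_k must be positive")
    t0 = time.perf_counter()
    D = distance_matrix(raster.trains, cfg.q)
    timings["distance_matrix"] = time.perf_counter() - t0
    io.write_matrix(outdir / "distance_matrix.csv", D.D)
    files["distance_matrix"] = str(outdir / "distance_matrix.csv")

    rates = raster.rates()
    t0 = time.perf_counter()
    rk: RankMatrix = rank_order(D, rates, cfg.rank_convention)
    timings["rank_order"] = time.perf_counter() - t0
    io.write_matrix(outdir / "rank_matrix.csv", rk.M)
    files["rank_matrix"] = str(outdir / "rank_matrix.csv")

    k = min(cfg.top_k, raster.n_neurons)
    # M is already permuted rate-descending, so the top-k block is the leading one
    M_top = rk.M[:k, :k]

    t0 = time.perf_counter()
    bars = rips_persistence(M_top, max_dim=1)
    timings["persistence"] = time.perf_counter() - t0
    io.write_barcode(outdir / "barcode.csv", bars)
    files["barcode"] = str(outdir / "barcode.csv")

    grid = default_grid(cfg.betti_grid)
    b0 = betti_curve(bars, 0, grid)
    b1 = betti_curve(bars, 1, grid)
    io.write_betti(outdir / "betti.csv", b0, b1)
    files["betti"] = str(outdir / "betti.csv")

    n_inf = sum(1 for b in bars if b.dim == 0 and b.death == inf)
    return {
        "n_selected": k,
        "beta0_at_zero": int(b0.counts[0]),
        "n_infinite_dim0_bars": n_inf,
        "n_dim1_bars": sum(1 for b in bars if b.dim == 1),
        "max_beta1": int(b1.counts.max()) if len(b1.counts) else 0,
    }


def run_full(config: PipelineConfig) -> RunManifest:
    """Execute the complete study for one target; see module docstring."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict = {}
    timings: dict = {}
    params = config.neuron_params()

    traj = generate_target(config.target)
    io.write_trajectory(outdir / "target.csv", traj)
    files["target"] = str(outdir / "target.csv")

    conn = init_connectivity(
        config.n_neurons,
        config.n_outputs,
        p=config.sparsity,
        g=config.gain,
        q_fb=config.feedback_strength,
        seed=config.seed_connectivity,
    )
    A_before = conn.A.copy()

    t0 = time.perf_counter()
    trained, history, state = train(
        conn, params, config.target, config.training, config.dt
    )
    timings["train"] = time.perf_counter() - t0
    assert np.array_equal(trained.A, A_before)  # recurrent core untouched by training
    io.write_history(outdir / "training_history.csv", history)
    files["training_history"] = str(outdir / "training_history.csv")
    io.save_connectivity(outdir / "connectivity.npz", trained, params)
    files["connectivity"] = str(outdir / "connectivity.npz")

    t0 = time.perf_counter()
    raster, times, z, state = run(
        trained,
        params,
        config.target.duration,
        config.dt,
        seed=config.seed_simulation,
        state=state,
    )
    timings["generate"] = time.perf_counter() - t0
    io.write_raster(outdir / "raster.csv", raster)
    files["raster"] = str(outdir / "raster.csv")
    io.write_trace(outdir / "output_trace.csv", times, z)
    files["output_trace"] = str(outdir / "output_trace.csv")

    # phase-aligned evaluation against the teacher clock
    zx, zy = evaluate_target(config.target, state.t - config.target.duration + times)
    z_t = np.column_stack([zx, zy])
    nrmse = float(
        np.sqrt(np.mean(np.sum((z - z_t) ** 2, axis=1)))
        / np.sqrt(np.mean(np.sum(z_t**2, axis=1)))
    )

    rt, rate = mean_rate_trace(raster, 0.02)
    io.write_trace(outdir / "rate_trace.csv", rt, rate[:, None])
    files["rate_trace"] = str(outdir / "rate_trace.csv")

    summary = _analyze(raster, config.analysis, outdir, files, timings)
    summary.update(
        {
            "nrmse": nrmse,
            "rate_min": float(rate.min()),
            "rate_max": float(rate.max()),
            "final_train_rmse": float(history[-1, 1]) if len(history) else None,
        }
    )

    checksums = {k: _sha256(v) for k, v in files.items()}
    manifest = RunManifest(
        config=config.to_dict(), files=files, checksums=checksums, timings=timings, summary=summary
    )
    io.write_json(outdir / "manifest.json", manifest.to_dict())
    for v in files.values():
        assert Path(v).exists()
    return manifest


def run_analysis_only(
    raster: SpikeRaster | str | Path,
    analysis: AnalysisConfig = AnalysisConfig(),
    output_dir: str | Path = "results/analysis",
) -> RunManifest:
    """Metric/topology stages on a stored or in-memory raster."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict = {}
    timings: dict = {}
    if not isinstance(raster, SpikeRaster):
        raster = io.read_raster(raster)
    summary = _analyze(raster, analysis, outdir, files, timings)
    checksums = {k: _sha256(v) for k, v in files.items()}
    manifest = RunManifest(
        config={"analysis": asdict(analysis)},
        files=files,
        checksums=checksums,
        timings=timings,
        summary=summary,
    )
    io.write_json(outdir / "manifest.json", manifest.to_dict())
    return manifest


def run_trajectory_eval(
    archive: str | Path | tuple[Connectivity, NeuronParams],
    target: TargetSpec,
    *,
    dt: float = 5e-5,
    seed: int = 3,
    settle: float = 0.0,
    state=None,
    align_phase: bool = False,
) -> dict:
    """Normalized RMSE between the autonomous readout and the target over one period.

    The error is normalized by the target RMS, so an untrained readout
    (W = 0, z_hat = 0) scores exactly 1.  By default the run is assumed to
    start phase-aligned with the target clock (t = 0 at a traversal start),
    which holds when continuing from a training whose schedule spans an
    integer number of periods (pass its final network ``state``).  From a
    cold start the autonomous oscillation has an arbitrary phase;
    ``align_phase=True`` scans circular shifts of the teacher and reports the
    best-matching normalized RMSE.
    """
    conn, params = io.load_connectivity(archive) if not isinstance(archive, tuple) else archive
    phase0 = 0.0 if state is None else state.t % target.duration
    if settle > 0:
        _, _, _, state = run(conn, params, settle, dt, seed=seed, state=state)
        phase0 = state.t % target.duration
    raster, times, z, state = run(conn, params, target.duration, dt, seed=seed, state=state)
    zx, zy = evaluate_target(target, phase0 + times)
    z_t = np.column_stack([zx, zy])
    if align_phase:
        best = np.inf
        n = len(times)
        for shift in range(0, n, max(n // 400, 1)):
            zx, zy = evaluate_target(target, phase0 + times + times[shift])
            cand = np.column_stack([zx, zy])
            err = np.sqrt(np.mean(np.sum((z - cand) ** 2, axis=1)))
            if err < best:
                best, z_t = err, cand
    err = np.sqrt(np.mean(np.sum((z - z_t) ** 2, axis=1)))
    norm = np.sqrt(np.mean(np.sum(z_t**2, axis=1)))
    return {
        "nrmse": float(err / norm),
        "times": times,
        "z_hat": z,
        "z_target": z_t,
        "raster": raster,
    }
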