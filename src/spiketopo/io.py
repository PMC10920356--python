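"""CSV / JSON / archive I/O for all pipeline artifacts.

Formats
-------
raster      : two columns ``neuron_id,spike_time_s`` sorted by neuron then time
trajectory  : ``time,x,y``
trace       : ``time,z1,z2``
matrix      : square CSV with a header row of neuron ids (symmetry validated
              on read)
barcode     : ``dim,birth,death`` with ``inf`` for essential classes
betti       : ``rho,beta0,beta1``
history     : ``t,rmse``
connectivity: NumPy ``.npz`` archive of A, U, W plus flat params
"""

from __future__ import annotations

import json
from math import inf
from pathlib import Path

import numpy as np
import pandas as pd

from .network import Connectivity, NeuronParams, SpikeRaster
from .targets import Trajectory
from .topology import BettiCurve, PersistenceBar


def write_raster(path, raster: SpikeRaster) -> None:
    rows = []
    for i, train in enumerate(raster.trains):
        for t in train:
            rows.append((i, t))
    df = pd.DataFrame(rows, columns=["neuron_id", "spike_time_s"])
    df.to_csv(path, index=False)


def read_raster(path, *, n_neurons: int | None = None, duration: float | None = None) -> SpikeRaster:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["neuron_id", "spike_time_s"]:
        raise ValueError(f"{path}: expected columns neuron_id,spike_time_s")
    bad = df[df["spike_time_s"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative spike time at line {bad.index[0] + 2}")
    n = n_neurons if n_neurons is not None else int(df["neuron_id"].max()) + 1 if len(df) else 0
    trains = [np.empty(0)] * n
    for i, grp in df.groupby("neuron_id"):
        trains[int(i)] = np.sort(grp["spike_time_s"].to_numpy())
    T = duration if duration is not None else (df["spike_time_s"].max() if len(df) else 1.0)
    return SpikeRaster(trains=trains, duration=float(T))


def write_trajectory(path, traj: Trajectory) -> None:
    pd.DataFrame({"time": traj.times, "x": traj.x, "y": traj.y}).to_csv(path, index=False)


def write_trace(path, times: np.ndarray, z: np.ndarray) -> None:
    z = np.atleast_2d(z)
    cols = {"time": times}
    for k in range(z.shape[1]):
        cols[f"z{k + 1}"] = z[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_matrix(path, M: np.ndarray) -> None:
    n = M.shape[0]
    pd.DataFrame(M, columns=[str(i) for i in range(n)]).to_csv(path, index=False)


def read_matrix(path) -> np.ndarray:
    M = pd.read_csv(path, float_precision="round_trip").to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    if not np.allclose(M, M.T, atol=1e-9):
        raise ValueError(f"{path}: matrix is not symmetric")
    return M


def write_barcode(path, bars: list[PersistenceBar]) -> None:
    df = pd.DataFrame(
        [(b.dim, b.birth, "inf" if b.death == inf else b.death) for b in bars],
        columns=["dim", "birth", "death"],
    )
    df.to_csv(path, index=False)


def read_barcode(path) -> list[PersistenceBar]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        PersistenceBar(int(r.dim), float(r.birth), inf if str(r.death) == "inf" else float(r.death))
        for r in df.itertuples()
    ]


def write_betti(path, b0: BettiCurve, b1: BettiCurve) -> None:
    pd.DataFrame({"rho": b0.grid, "beta0": b0.counts, "beta1": b1.counts}).to_csv(
        path, index=False
    )


def write_history(path, history: np.ndarray) -> None:
    pd.DataFrame(history, columns=["t", "rmse"]).to_csv(path, index=False)


def save_connectivity(path, conn: Connectivity, params: NeuronParams) -> None:
    np.savez_compressed(
        path,
        A=conn.A,
        U=conn.U,
        W=conn.W,
        meta=np.array(
            json.dumps(
                {
                    "sparsity": conn.sparsity,
                    "gain": conn.gain,
                    "feedback_strength": conn.feedback_strength,
                    "params": vars(params) if not hasattr(params, "__dataclass_fields__") else {
                        k: getattr(params, k) for k in params.__dataclass_fields__
                    },
                }
            )
        ),
    )


def load_connectivity(path) -> tuple[Connectivity, NeuronParams]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        conn = Connectivity(
            A=z["A"],
            U=z["U"],
            W=z["W"],
            sparsity=meta["sparsity"],
            gain=meta["gain"],
            feedback_strength=meta["feedback_strength"],
        )
    return conn, NeuronParams(**meta["params"])


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
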