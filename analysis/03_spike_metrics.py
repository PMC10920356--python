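"""Victor-Purpura distance and rank-order matrices for the trained-network rasters.

Reads the rasters stored by 02_train_networks.py, recomputes D and M for each
target (they are also written by the pipeline; recomputing here demonstrates
the analysis-only entry point), and renders the two matrix families side by
side as heat maps under results/metrics/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from spiketopo import io
from spiketopo.metrics import distance_matrix, rank_order
from spiketopo.targets import SHAPES

RUNS = Path(__file__).resolve().parent.parent / "results" / "runs"
OUT = Path(__file__).resolve().parent.parent / "results" / "metrics"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(2, 4, figsize=(16, 7.5))
    stats = []
    for col, shape in enumerate(SHAPES):
        raster_path = RUNS / shape / "raster.csv"
        if not raster_path.exists():
            print(f"missing {raster_path}; run 02_train_networks.py first")
            return
        raster = io.read_raster(raster_path, duration=1.0)
        D = distance_matrix(raster.trains, q=1.0)
        rk = rank_order(D, raster.rates())
        io.write_matrix(OUT / f"D_{shape}.csv", D.D)
        io.write_matrix(OUT / f"M_{shape}.csv", rk.M)
        off = D.D[~np.eye(D.D.shape[0], dtype=bool)]
        stats.append(
            {"shape": shape, "D_max": off.max(), "D_median": np.median(off)}
        )
        axes[0, col].imshow(D.D, cmap="jet")
        axes[0, col].set_title(f"D — {shape}")
        axes[1, col].imshow(rk.M, cmap="jet")
        axes[1, col].set_title(f"M — {shape}")
    fig.tight_layout()
    fig.savefig(OUT / "matrices.png", dpi=110)
    df = pd.DataFrame(stats)
    df.to_csv(OUT / "summary.csv", index=False)
    print(df.to_string(index=False))
    print("\nD is symmetric with zero diagonal; M holds its normalized descending")
    print("ranks (largest distance -> 0), reindexed by firing rate.")
    print(f"Artifacts in {OUT}")


if __name__ == "__main__":
    main()
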