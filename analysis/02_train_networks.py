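"""FORCE-train one reservoir per target and generate 1 s of autonomous drawing.

For each of the four targets this trains a 1000-neuron LIF reservoir with
the calibrated defaults, freezes the readout, simulates one autonomous trial,
and stores the raster, readout trace, rate trace and trained archive under
results/runs/<shape>/.  The run summary (drawing error, rate band, petal
excursions) is collected in results/runs/summary.csv.

This is the expensive stage (a few minutes per target on one CPU); the later
scripts consume its artifacts.
"""

import sys
from pathlib import Path

import pandas as pd

from spiketopo import io
from spiketopo.force import TrainConfig
from spiketopo.pipeline import PipelineConfig, run_full
from spiketopo.targets import SHAPES, TargetSpec

OUT = Path(__file__).resolve().parent.parent / "results" / "runs"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for shape in SHAPES:
        cfg = PipelineConfig(
            target=TargetSpec(shape),
            training=TrainConfig(seed=seed + 1),
            seed_connectivity=seed,
            seed_simulation=seed + 2,
            output_dir=str(OUT / shape),
        )
        manifest = run_full(cfg)
        s = manifest.summary
        rows.append(
            {
                "shape": shape,
                "nrmse": round(s["nrmse"], 3),
                "rate_min_hz": round(s["rate_min"], 1),
                "rate_max_hz": round(s["rate_max"], 1),
                "n_dim1_bars": s["n_dim1_bars"],
                "train_s": round(manifest.timings["train"], 1),
            }
        )
        print(f"{shape}: nrmse {s['nrmse']:.3f}, rate band "
              f"[{s['rate_min']:.1f}, {s['rate_max']:.1f}] Hz", flush=True)
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "summary.csv", index=False)
    print("\n" + df.to_string(index=False))
    print(f"\nArtifacts in {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
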