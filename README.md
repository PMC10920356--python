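# spiketopo

Topological analysis of spike trains in recurrent spiking networks trained to
draw closed planar curves.

A recurrent network of *N* leaky integrate-and-fire (LIF) neurons with
double-exponential synapses is trained — by FORCE learning, i.e. recursive
least squares (RLS) on the linear readout only — to autonomously generate a
two-dimensional target trajectory `z(t) = [x(t), y(t)]`: a circle or a two-,
three-, or four-petal polar rose, one closed traversal per 1 s trial.  The
spike trains of the trained network are then characterized geometrically:

1. **Victor–Purpura (VP) distances.**  Every pair of spike trains gets an
   edit-cost distance (insert/delete a spike: cost 1; shift by time *t*: cost
   *q·t*, default *q* = 1 s⁻¹), giving a symmetric distance matrix **D**.
2. **Rank-order transform.**  The above-diagonal entries of **D** are
   replaced by their ranks (largest distance → 0), mirrored, normalized by
   *N(N−1)/2*, and the rows/columns are re-indexed by descending firing rate,
   giving the matrix **M** — invariant to any monotone transform of **D**.
3. **Persistent homology.**  The 100 most active neurons, with dissimilarity
   **M**, are fed to a Vietoris–Rips filtration: vertices are present from
   ρ = 0, the edge (i, j) enters at ρ = M_ij, triangles at the largest of
   their edge values.  The output is a persistence barcode (dimension 0:
   connected components; dimension 1: loops) and the Betti curves β₀(ρ),
   β₁(ρ).

Everything is generated internally — there are no external datasets.  A
synthetic-raster module produces petal-modulated Poisson surrogates with the
same statistical structure as the trained networks (per-neuron rates in a
20–80 Hz band, K distinct active phases for a K-petal target), so the metric
and topology stages can be exercised without training.

## Model

Membrane potentials follow

    τ_m dv_i/dt = v_rest − v_i + I_bias + Σ_j ω_ij r_j ,    ω = A + U Wᵀ,

with threshold/reset spiking, an absolute refractory period, and filtered
rates

    dr_i/dt = −r_i/τ_d + h_i ,
    dh_i/dt = −h_i/τ_r + (1/τ_r τ_d) Σ_k δ(t − t_k^(i)) .

The readout `ẑ = W r` feeds back through fixed random weights **U**; only
**W** is trained, by RLS:

    e = ẑ − z ,   P ← P − (P r rᵀ P)/(1 + rᵀ P r) ,   W ← W − e (P r)ᵀ ,

with `P(0) = I/α`.  The sparse recurrent matrix **A** (Gaussian entries, std
g/√(pN)) is never modified; the trained readout perturbs the effective
coupling only through the rank-2 term `U Wᵀ`.

## Worked example

Train a 1000-neuron reservoir on the four-petal rose, draw for one second,
and analyze the spikes (about half a minute on one CPU):

```python
from spiketopo import (TargetSpec, TrainConfig, init_connectivity, train, run,
                       mean_rate_trace, count_rate_excursions, distance_matrix,
                       rank_order, rips_persistence, default_neuron_params)
from spiketopo.pipeline import DEFAULT_GAIN, DEFAULT_FEEDBACK

params = default_neuron_params()            # bias calibrated to a 38 Hz tonic rate
conn = init_connectivity(1000, 2, p=0.1, g=DEFAULT_GAIN, q_fb=DEFAULT_FEEDBACK, seed=11)
trained, history, state = train(conn, params, TargetSpec("rose4"), TrainConfig(seed=12))
raster, t, z, _ = run(trained, params, 1.0, seed=13, state=state)

_, rate = mean_rate_trace(raster, 0.02)
print(f"rate band [{rate.min():.1f}, {rate.max():.1f}] Hz,",
      f"{count_rate_excursions(rate)} petal excursions")

D = distance_matrix(raster.trains, q=1.0)
M = rank_order(D, raster.rates()).M
bars = rips_persistence(M[:100, :100], max_dim=1)
print(f"{sum(b.dim == 0 for b in bars)} component bars,",
      f"{sum(b.dim == 1 for b in bars)} loop bars")
```

Output:

```
rate band [32.3, 75.3] Hz, 4 petal excursions
100 component bars, 332 loop bars
```

The population rate rises and falls once per petal (4 excursions within the
20–80 Hz band), the dim-0 barcode starts from the 100 selected neurons and
collapses to a single infinite component, and several hundred transient
dim-1 loops appear along the filtration.  The same network trained on the
circle holds a narrow 70–83 Hz band with no petal structure and redraws its
target with a normalized RMSE of about 0.02.

## Analysis scripts

The numbered drivers under `analysis/` run the study end to end and write
tables and figures under `results/`:

| script | what it does |
| --- | --- |
| `01_targets.py` | generate and verify the four closed target curves |
| `02_train_networks.py` | FORCE-train one reservoir per target, store rasters and traces |
| `03_spike_metrics.py` | VP distance and rank-order matrices for the stored rasters |
| `04_topology.py` | barcodes and Betti curves of the top-100 rank matrices |
| `05_surrogates.py` | petal-modulated surrogate rasters through the same analysis |

A `spiketopo` CLI wraps the same pipeline (`synth`, `train`, `generate`,
`analyze`, `full`, `eval` subcommands, all seeded and config-driven).

## Layout

```
src/spiketopo/        library: targets, network, force, metrics, topology,
                      synthetic, pipeline, calibrate, io, cli
analysis/             numbered study drivers (write to results/)
scripts/acceptance.py headline-number reproduction
tests/                pytest suite (unit, property, acceptance)
docs/methods.md       modeling and calibration notes
```
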