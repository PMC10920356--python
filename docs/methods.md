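# Methods

## Network model

The reservoir is a recurrent network of *N* leaky integrate-and-fire neurons.
Voltages (mV) obey

    τ_m dv_i/dt = v_rest − v_i + I_bias + Σ_j ω_ij r_j ,

with threshold v_th, reset v_reset, and an absolute refractory period during
which the voltage is clamped at v_reset and input is ignored.  Spikes drive a
double-exponential synaptic filter (rise τ_r, decay τ_d) whose single-spike
response has unit time-integral, so the filtered rate r_i is measured in s⁻¹
and its time average approximates the firing rate in Hz.  The effective
coupling is ω = A + U Wᵀ: a fixed sparse Gaussian recurrent matrix **A**
(connection probability *p*, nonzero entries of standard deviation g/√(pN)),
fixed uniform feedback weights **U** ∈ [−q_fb, q_fb]^(N×M) from the M = 2
readouts, and the trained readout **W** (zero before training).  Integration
is forward Euler for the voltage with exact exponential integration of the
(r, h) synapse pair; the optimized simulation loop is verified step-for-step
against the reference `step()` update in the tests.

Default single-neuron constants (all overridable): τ_m = 10 ms,
v_rest = −65 mV, v_th = −40 mV, v_reset = −65 mV, refractory 2 ms,
τ_r = 2 ms, τ_d = 20 ms, dt = 0.05 ms.  Note that the refractory period and
the synaptic rise constant are two distinct parameters even though both are
conventionally written τ_r.

### Operating point and calibration

With the constants above and zero bias the network is silent (the resting
level sits 25 mV below threshold), so the bias current is a calibrated
parameter.  `calibrate.bias_for_rate` inverts the closed-form LIF rate

    rate = 1 / (τ_ref + τ_m ln((v_∞ − v_reset)/(v_∞ − v_th))),  v_∞ = v_rest + I_bias,

and the experiment defaults place the uncoupled tonic rate at 38 Hz
(I_bias ≈ 25.6 mV).  The drawing networks then operate in a feedback-driven
regime: between petals of a rose target the output amplitude |z| is small,
the feedback drive vanishes, and the population rate falls toward its
intrinsic value; during a petal the feedback lifts part of the population to
high rates.  This single operating point reproduces both observed regimes —
a narrow high band (≈70–83 Hz) for the circle, whose |z| is constant, and
wide per-petal rate excursions (≈30–80 Hz) for the roses.  The coupling gain
(g = 0.08) and feedback strength (q_fb = 90) were fixed once by scanning a
small grid and keeping the values whose circle band best matched the target
band while the rose networks trained stably; `calibrate.calibrate_gain`
documents the same procedure as a reusable helper (largest gain whose
untrained autonomous rate trace stays inside a requested band).

## Targets

Four closed polar curves with amplitude R = 1 (the readout absorbs scale):
a circle, and roses r = R sin(kφ) with two petals (k = 2 on the restricted
angular domain φ ∈ [0, π/2] ∪ [π, 3π/2], the excluded intervals skipped by a
continuous time mapping), three petals (r = R sin(1.5φ)), and four petals
(k = 2 on the full domain).  Time is parameterized so one closed traversal
spans exactly the 1 s trial; the three-petal rose closes at φ = 2π (it
starts and ends at the origin) and shows exactly three radial lobes over
that span, which is the span used here.  Closure is verified to < 10⁻⁹·R.

## FORCE training

Only **W** is trained.  After a 0.2 s settle period, every Δt = 2 ms the
error e = W r − z (teacher evaluated at the update instant) drives the RLS
update of the inverse-correlation estimate P (initialized to I/α, α = 0.05)
followed by W ← W − e (P r)ᵀ with the updated P.  P is re-symmetrized after
every update to keep it positive definite over 10³–10⁴ updates; the suite
checks P against the closed form (αI + Σ r rᵀ)⁻¹.  Training runs 6 s
(six traversals) by default; an optional ‖ΔW‖ tolerance stops earlier.  The
feedback carries the network's own readout during training (classic FORCE);
full teacher forcing is available as a flag.  Because the schedule spans an
integer number of periods, the generation trial that follows is phase-aligned
with the teacher clock, and the drawing error is reported as RMSE normalized
by the target RMS (untrained readout ⇒ 1.0).  Trained circle networks reach
a normalized RMSE of ≈0.02; autonomous rose generation preserves the petal
rate structure robustly but its phase can drift relative to the teacher
clock over the trial, so shape-level comparison for roses uses the
phase-alignment option of the evaluation helper.

## Victor–Purpura analysis

The VP distance is computed with the standard dynamic program over the two
spike sequences (insert/delete cost 1, shift cost q per second, q = 1 s⁻¹
by default; spike times in seconds over 1 s trials).  The distance matrix is
computed once per unordered pair (numba-compiled inner loop).  Rank
ordering replaces the above-diagonal distances by ranks — by default in
*descending* order (largest distance → rank 0), so larger distances map to
smaller entries of **M**; the literal ascending convention is available via
a flag.  Exact ties are broken by lexicographic pair order.  Entries are
normalized by N(N−1)/2 and rows/columns permuted by descending firing rate
(rate ties prefer the lower index).  The diagonal of **M** is set to the
convention-consistent extreme (1 under the default) and never participates
in ranking.  Ranking is performed on the full population first; the
top-100-active block is then extracted for topology.

## Persistent homology

The Rips filtration of **M** enters edge (i, j) at ρ = M_ij and a triangle
at the maximum of its three edges.  Dimension 0 is computed by union–find
over weight-sorted edges: every vertex contributes a bar born at 0, each
merging edge ends one bar, and exactly one bar is infinite (zero-persistence
dim-0 merges are retained so the barcode always starts from n bars — the
rank matrix contains one exact 0 entry by construction).  Dimension 1 uses
GF(2) boundary-matrix reduction with columns stored as integer bitmasks over
the edge order; a reduced triangle column pairs its pivot edge (cycle birth)
with the triangle (death), and zero-persistence dim-1 pairs are dropped.  In
a complete filtration every 1-cycle dies, so there are no infinite dim-1
bars.  Betti curves count bars on the half-open interval [birth, death) over
a 512-point grid on [0, 1] by default.  The implementation is validated
against an independent textbook reduction (dense full boundary matrix) on
random 12–15-point matrices, exact to the filtration values, and against
hand-reduced cases (e.g. the unit square's single dim-1 bar [1, √2]).
For 100 points the dim-1 reduction takes about a second.

## Synthetic rasters

The surrogate generator emulates the trained networks' raster statistics
without training.  Each neuron receives one preferred phase φ_i, clustered
on the K petal phases with von-Mises jitter (concentration 20), and an
inhomogeneous Poisson intensity with a single active phase per trial,
λ_i(t) = B + A·max(0, cos(2πt/T − φ_i))^c with concentration exponent
c = 8.  A and B are set so the population rate trace spans exactly the
requested band (default 20–80 Hz).  Spikes are drawn by thinning.  The
surrogates reproduce the petal-locked excursion count and the rate band but
not the trained networks' VP-matrix fine structure or any recurrent
dynamics — passing surrogate-based tests validates the metric/topology
stages, not the network model.

Rate traces are computed by binning all spikes at 1 ms, averaging over a
sliding 20 ms window (edge windows normalized by their actual overlap), and
dividing by the neuron count.  Excursions are counted circularly (the trial
is one period) on the smoothed trace with a prominence threshold of 0.3 of
the trace span.

## Problem sizes and numerical choices

Scaled experiments use N = 1000 neurons, p = 0.1, dt = 0.05 ms, 6 s of
training and 1 s of generation — chosen as the smallest configuration that
reproduces the study's rate-band and petal-structure observations stably
across seeds.  Divergent training (non-finite or unbounded error) raises
with a hint to recalibrate g or α.  All randomness flows through explicit
integer seeds (connectivity, training, simulation); fixed seeds give
byte-identical CSV artifacts.

## Known limitations

- Spike times are recorded at the end of the integration step (no sub-step
  interpolation); at q = 1 s⁻¹ the VP distances are insensitive to sub-dt
  jitter.
- Autonomous rose drawing can drift in phase relative to the teacher clock;
  rate-structure statistics are unaffected.
- Homology is computed only in dimensions 0 and 1, on the full clique
  complex up to triangles.
- Self-connections in **A** are drawn like any other entry.
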