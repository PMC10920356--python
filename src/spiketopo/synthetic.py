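"""Surrogate spike rasters with petal-locked rate modulation.

The trained drawing networks show two robust statistical features: per-neuron
firing rates spread over roughly 20-80 Hz, and, for K-petal targets, K
distinct active phases per 1 s trial with different neurons active in
different phases.  The generator emulates exactly that structure so the
metric and topology stages can be exercised (and their acceptance properties
checked) without running a training.

Each neuron i receives a preferred phase phi_i centered on one of the K petal
phases (with von-Mises jitter) and an inhomogeneous Poisson intensity with a
single active phase per trial,

    lambda_i(t) = B + A * max(0, cos(2 pi t / T - phi_i))**c ,

so different petals are carried by different neurons, as in the trained
networks.  The concentration exponent c sharpens the active phase.  A and B are
set so that the *population* rate trace spans exactly the requested band
[low, high]: its minimum (between petals) equals ``low`` and its peak equals
``high``.  Spikes are drawn by thinning a homogeneous Poisson process at the
per-neuron peak intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SpikeRaster

__all__ = ["SynthSpec", "homogeneous_poisson", "petal_modulated_raster", "jittered_copies"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a petal-modulated surrogate raster.

    rate_band is the (low, high) span of the population 20-ms rate trace in
    Hz; phase_concentration is the tuning exponent c (higher = sharper
    petals); phase_jitter_kappa is the von-Mises concentration of the
    per-neuron preferred-phase scatter around its petal center.
    """

    n_neurons: int = 300
    duration: float = 1.0
    petal_count: int = 3
    rate_band: tuple[float, float] = (20.0, 80.0)
    phase_concentration: float = 8.0
    phase_jitter_kappa: float = 20.0
    modulation_depth: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.rate_band
        if not 0 <= low < high:
            raise ValueError("rate_band must satisfy 0 <= low < high")
        if self.petal_count < 1:
            raise ValueError("petal_count must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def homogeneous_poisson(
    n: int,
    rate: float,
    T: float,
    seed: int | np.random.Generator = 0,
    *,
    refractory: float = 0.0,
) -> SpikeRaster:
    """n independent homogeneous Poisson spike trains of the given rate over [0, T].

    Optional absolute refractoriness is enforced by thinning (spikes closer
    than ``refractory`` seconds to the previous kept spike are discarded).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n):
        if rate == 0:
            trains.append(np.empty(0))
            continue
        # draw enough exponential ISIs to cover T with margin
        n_draw = max(int(rate * T * 1.5) + 20, 20)
        t = np.cumsum(rng.exponential(1.0 / rate, size=n_draw))
        while t[-1] < T:
            t = np.concatenate([t, t[-1] + np.cumsum(rng.exponential(1.0 / rate, size=n_draw))])
        t = t[t < T]
        if refractory > 0 and len(t) > 1:
            kept = [t[0]]
            for s in t[1:]:
                if s - kept[-1] >= refractory:
                    kept.append(s)
            t = np.asarray(kept)
        trains.append(t)
    return SpikeRaster(trains=trains, duration=T)


def petal_intensities(spec: SynthSpec, t: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Analytic per-neuron intensity lambda_i(t), shape (n_neurons, len(t))."""
    bump = np.maximum(
        0.0, np.cos(2 * np.pi * t[None, :] / spec.duration - phases[:, None])
    ) ** spec.phase_concentration
    low, high = spec.rate_band
    pop = bump.mean(axis=0)
    span = pop.max() - pop.min()
    if spec.modulation_depth == 0 or span == 0:
        return np.full_like(bump, 0.5 * (low + high))
    # affine scale so the population trace spans exactly [low, high]
    depth = spec.modulation_depth
    A = depth * (high - low) / span
    B = low + (1 - depth) * 0.5 * (high - low) - A * pop.min()
    return np.maximum(A * bump + B, 0.0)


def preferred_phases(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """One preferred phase per neuron: uniform over the K petal centers plus jitter."""
    k = spec.petal_count
    centers = 2 * np.pi * rng.integers(0, k, size=spec.n_neurons) / k
    jitter = rng.vonmises(0.0, spec.phase_jitter_kappa, size=spec.n_neurons)
    return np.mod(centers + jitter, 2 * np.pi)


def petal_modulated_raster(spec: SynthSpec) -> tuple[SpikeRaster, np.ndarray]:
    """Draw a surrogate raster; returns (raster, preferred phases).

    With petal_count = 1 and modulation_depth = 0 this degenerates to a
    homogeneous Poisson raster at the mid-band rate.
    """
    rng = np.random.default_rng(spec.seed)
    phases = preferred_phases(spec, rng)
    grid = np.linspace(0.0, spec.duration, 2001)
    lam = petal_intensities(spec, grid, phases)
    lam_max = lam.max(axis=1)
    trains = []
    for i in range(spec.n_neurons):
        if lam_max[i] <= 0:
            trains.append(np.empty(0))
            continue
        n_exp = rng.poisson(lam_max[i] * spec.duration)
        cand = np.sort(rng.uniform(0.0, spec.duration, size=n_exp))
        lam_at = np.interp(cand, grid, lam[i])
        keep = rng.uniform(0.0, lam_max[i], size=n_exp) < lam_at
        trains.append(cand[keep])
    return SpikeRaster(trains=trains, duration=spec.duration), phases


def jittered_copies(
    train, sigma: float, n: int, seed: int | np.random.Generator = 0, *, T: float | None = None
) -> list[np.ndarray]:
    """n copies of a spike train with iid zero-mean Gaussian jitter of scale sigma.

    Jittered times are clipped to [0, T] (T defaults to the last spike time)
    and re-sorted; spike counts are preserved.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    t = np.asarray(train, dtype=float)
    rng = np.random.default_rng(seed)
    upper = float(t[-1]) if T is None and t.size else (T if T is not None else 0.0)
    out = []
    for _ in range(n):
        s = t + rng.normal(0.0, sigma, size=t.shape) if sigma > 0 else t.copy()
        out.append(np.sort(np.clip(s, 0.0, upper)))
    return out
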