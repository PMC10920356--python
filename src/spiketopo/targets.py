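"""Closed planar target curves for the drawing task.

The teacher signal is a two-dimensional trajectory z(t) = [x(t), y(t)] tracing
one of four closed polar figures: a circle and two-, three-, and four-petal
roses.  All curves share the polar form r = R*sin(k*phi) (the circle being the
degenerate constant-radius case) and are reparameterized in time so that one
full closed traversal occupies exactly the trial duration T.

The two-petal rose is the four-petal curve restricted to the angular domain
phi in [0, pi/2] union [pi, 3*pi/2]; the excluded intervals are skipped with a
continuous time mapping so the drawn trajectory has no jumps (both petal
boundaries sit at the origin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SHAPES = ("circle", "rose2", "rose3", "rose4")

#: angular span (radians) covered by one closed traversal of each curve
_ANGULAR_SPAN = {"circle": 2 * np.pi, "rose2": np.pi, "rose3": 2 * np.pi, "rose4": 2 * np.pi}


@dataclass(frozen=True)
class TargetSpec:
    """Specification of a closed planar target curve.

    Parameters
    ----------
    shape_id : {"circle", "rose2", "rose3", "rose4"}
    amplitude : float
        Radial amplitude R in output units (default 1; the readout weights
        absorb any overall scale).
    duration : float
        Trial length T in seconds; one closed traversal spans [0, T].
    dt : float
        Sample step in seconds (matches the simulator step by default).
    base_frequency : float or None
        f1 in Hz.  If None it is taken as 1/T so a single traversal fills the
        trial; a value is stored for provenance but the traversal is always
        rescaled onto [0, T].
    """

    shape_id: str
    amplitude: float = 1.0
    duration: float = 1.0
    dt: float = 5e-5
    base_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.shape_id not in SHAPES:
            raise ValueError(f"unknown shape_id {self.shape_id!r}; expected one of {SHAPES}")
        if self.amplitude <= 0:
            raise ValueError("amplitude R must be positive")
        if self.duration <= 0:
            raise ValueError("duration T must be positive")
        if not 0 < self.dt < self.duration:
            raise ValueError("require 0 < dt < T")


@dataclass
class Trajectory:
    """Time-sampled planar curve: equal-length arrays times, x, y (seconds)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x, y must have equal length")

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of samples."""
        return np.column_stack([self.x, self.y])

    def closure_error(self) -> float:
        """Euclidean distance between the first and last sampled point."""
        return float(np.hypot(self.x[-1] - self.x[0], self.y[-1] - self.y[0]))


def petal_count(shape_id: str) -> int:
    """Number of petals (distinct radial lobes) of the curve: circle -> 1, roseK -> K."""
    table = {"circle": 1, "rose2": 2, "rose3": 3, "rose4": 4}
    try:
        return table[shape_id]
    except KeyError:
        raise ValueError(f"unknown shape_id {shape_id!r}; expected one of {SHAPES}") from None


def _phase_of_time(shape_id: str, s: np.ndarray) -> np.ndarray:
    """Map normalized time s = t/T in [0, 1] to the polar angle phi.

    For rose2 the excluded half of the angular domain is skipped: the first
    half of the trial covers [0, pi/2], the second half covers [pi, 3*pi/2].
    """
    if shape_id == "rose2":
        s = np.asarray(s, dtype=float)
        phi = np.where(s < 0.5, np.pi * s, np.pi + np.pi * (s - 0.5))
        return phi
    return _ANGULAR_SPAN[shape_id] * np.asarray(s, dtype=float)


def _polar_radius(shape_id: str, phi: np.ndarray, R: float) -> np.ndarray:
    if shape_id == "circle":
        return np.full_like(np.asarray(phi, dtype=float), R)
    k_half = {"rose2": 2.0, "rose3": 1.5, "rose4": 2.0}[shape_id]
    return R * np.sin(k_half * phi)


def evaluate_target(spec: TargetSpec, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (x, y) of the target at arbitrary times (wrapped modulo T)."""
    s = np.mod(np.asarray(t, dtype=float), spec.duration) / spec.duration
    phi = _phase_of_time(spec.shape_id, s)
    r = _polar_radius(spec.shape_id, phi, spec.amplitude)
    return r * np.cos(phi), r * np.sin(phi)


def generate_target(spec: TargetSpec) -> Trajectory:
    """Sample one closed traversal of the target curve on [0, T].

    The endpoint t = T is included so closure (first point == last point) can
    be checked directly on the samples.
    """
    n = int(round(spec.duration / spec.dt))
    times = np.linspace(0.0, spec.duration, n + 1)
    s = times / spec.duration
    # evaluate at s exactly (s[-1] == 1), not wrapped, to land on the closure point
    phi = _phase_of_time(spec.shape_id, np.minimum(s, 1.0))
    r = _polar_radius(spec.shape_id, phi, spec.amplitude)
    return Trajectory(times=times, x=r * np.cos(phi), y=r * np.sin(phi))
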