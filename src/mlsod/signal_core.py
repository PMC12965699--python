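"""First-order temporal filters and rectifiers shared by every detector.

All detectors in this package are built from the same three primitives: a
first-order high-pass filter that strips the standing luminance level, a
first-order low-pass filter that provides the temporal delay of the
correlator arms, and half/full-wave rectifiers that split the signal into
ON (brightening) and OFF (darkening) channels.

Filters are discretized with the exact exponential (zero-order hold) update

    y_t = y_{t-1} + alpha * (x_t - y_{t-1}),   alpha = 1 - exp(-dt / tau)

which is unconditionally stable for any step/time-constant ratio and exact
for piecewise-constant input held over each frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilterState",
    "low_pass_step",
    "high_pass_step",
    "half_wave_on",
    "half_wave_off",
    "full_wave",
]


@dataclass
class FilterState:
    """State of a first-order low-pass filter over a signal array.

    Parameters
    ----------
    tau : float
        Time constant in seconds. Must be positive.
    dt : float
        Sampling period in seconds. Must be positive.
    y_prev : ndarray
        Previous filter output; initialized to zeros matching the first
        input's shape if not supplied.
    """

    tau: float
    dt: float
    y_prev: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    @property
    def alpha(self) -> float:
        """Per-step smoothing factor 1 - exp(-dt/tau)."""
        return 1.0 - float(np.exp(-self.dt / self.tau))


def low_pass_step(x: np.ndarray, state: FilterState) -> np.ndarray:
    """Advance the low-pass filter one frame and return its output.

    DC gain is exactly 1: a constant input converges monotonically to
    itself from any initial state.
    """
    x = np.asarray(x, dtype=float)
    if state.y_prev is None:
        state.y_prev = np.zeros_like(x)
    elif state.y_prev.shape != x.shape:
        raise ValueError(
            f"state shape {state.y_prev.shape} does not match input {x.shape}"
        )
    y = state.y_prev + state.alpha * (x - state.y_prev)
    state.y_prev = y
    return y


def high_pass_step(x: np.ndarray, state: FilterState) -> np.ndarray:
    """Advance the complementary high-pass filter one frame.

    Implemented as ``x - LP_tau(x)`` so that HP(x) + LP(x) == x exactly at
    every step and constant inputs are rejected in steady state.
    """
    return np.asarray(x, dtype=float) - low_pass_step(x, state)


def half_wave_on(x: np.ndarray) -> np.ndarray:
    """ON rectifier: positive part, cutoff at 0."""
    return np.maximum(x, 0.0)


def half_wave_off(x: np.ndarray) -> np.ndarray:
    """OFF rectifier: magnitude of the negative part, cutoff at 0."""
    return np.maximum(-np.asarray(x, dtype=float), 0.0)


def full_wave(x: np.ndarray) -> np.ndarray:
    """Full-wave rectifier |x|; equals half_wave_on(x) + half_wave_off(x)."""
    return np.abs(x)
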