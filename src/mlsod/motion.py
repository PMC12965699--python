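"""Nondirectional visual motion extraction (stage 1 of the model).

Two detector families are provided, both operating per ON/OFF channel on
the retina lattice:

* **Two-arm EMD** (Hassenstein–Reichardt correlator): per adjacent lattice
  pair along an axis, the delayed signal of one point is multiplied by the
  undelayed signal of the other; subtracting the mirror half-correlator
  gives a signed directional output. Full-wave rectifying and summing the
  horizontal and vertical outputs gives the nondirectional motion field.

* **Three-arm detector** (T4/T5-like): three colinear inputs — a delayed
  preferred-side arm ``a``, a fast center ``b`` and a delayed null-side
  arm ``c`` — combined as ``a * b / (c + delta)``, where the divisive
  null-side arm sharpens direction selectivity and the small constant
  ``delta`` guards the division. Four detectors (left/right/up/down) per
  site are pooled by taking, per axis, the larger of the two opposed
  outputs and summing across axes; an optional adaptive threshold zeroes,
  per axis and per frame, every output below half the axis-wide maximum.

Both detectors share the same first-order low-pass delay filter (tau_LP1)
and are null for any static scene once the delay filter has converged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_core import FilterState, full_wave, low_pass_step

__all__ = [
    "MotionField",
    "ThreeArmParams",
    "emd_correlate",
    "emd_step",
    "pool_nondirectional_two_arm",
    "three_arm_correlate",
    "three_arm_step",
    "pool_nondirectional_three_arm",
]

AXIS = {"horizontal": 1, "vertical": 0}


@dataclass
class MotionField:
    """Per-location nondirectional motion magnitudes for one channel."""

    values: np.ndarray  # nonnegative, retina lattice
    channel: str = "OFF"  # "ON" or "OFF"


@dataclass
class ThreeArmParams:
    """Parameters of the three-arm detector and its pooling stage."""

    delta: float = 0.05
    adaptive_threshold_enabled: bool = False
    threshold_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")


# ---------------------------------------------------------------------------
# Two-arm EMD
# ---------------------------------------------------------------------------

def emd_correlate(x: np.ndarray, delayed: np.ndarray, axis: str) -> np.ndarray:
    """Signed correlator output for adjacent pairs along an axis.

    For points A (lower index) and B = A+1:
    ``out[A] = delayed[A] * x[B] - x[A] * delayed[B]``; positive sign means
    motion toward increasing index. The output sits at the leading (lower
    index) location; the final row/column along the axis is zero.
    """
    ax = AXIS[axis]
    if x.shape[ax] < 2:
        raise ValueError("lattice thinner than 2 along the detector axis")
    out = np.zeros_like(x, dtype=float)
    a = [slice(None), slice(None)]
    b = [slice(None), slice(None)]
    a[ax] = slice(None, -1)
    b[ax] = slice(1, None)
    a, b = tuple(a), tuple(b)
    out[a] = delayed[a] * x[b] - x[a] * delayed[b]
    return out


def emd_step(x: np.ndarray, lp_state: FilterState, axis: str) -> np.ndarray:
    """Advance the delay filter one frame and return the signed EMD output."""
    delayed = low_pass_step(x, lp_state)
    return emd_correlate(x, delayed, axis)


def pool_nondirectional_two_arm(h: np.ndarray, v: np.ndarray,
                                channel: str = "OFF") -> MotionField:
    """Full-wave rectify and sum signed horizontal+vertical EMD outputs."""
    if h.shape != v.shape:
        raise ValueError("horizontal and vertical maps must share a shape")
    return MotionField(values=full_wave(h) + full_wave(v), channel=channel)


# ---------------------------------------------------------------------------
# Three-arm detector
# ---------------------------------------------------------------------------

def three_arm_correlate(
    x: np.ndarray,
    delayed: np.ndarray,
    axis: str,
    preferred_direction: int,
    delta: float = 0.05,
) -> np.ndarray:
    """Three-arm output ``a*b/(c+delta)`` assigned to the center position.

    With ``preferred_direction=+1`` (motion toward increasing index) the
    delayed preferred-side arm is the lower-index neighbor, the fast center
    is the site itself, and the delayed null-side arm is the higher-index
    neighbor; roles mirror for ``-1``. Border positions output 0.
    """
    ax = AXIS[axis]
    if x.shape[ax] < 3:
        raise ValueError("lattice thinner than 3 along the detector axis")
    out = np.zeros_like(x, dtype=float)
    lo = [slice(None), slice(None)]
    mid = [slice(None), slice(None)]
    hi = [slice(None), slice(None)]
    lo[ax] = slice(None, -2)
    mid[ax] = slice(1, -1)
    hi[ax] = slice(2, None)
    lo, mid, hi = tuple(lo), tuple(mid), tuple(hi)
    if preferred_direction > 0:
        a, c = delayed[lo], delayed[hi]
    else:
        a, c = delayed[hi], delayed[lo]
    out[mid] = a * x[mid] / (c + delta)
    return out


def three_arm_step(
    x: np.ndarray,
    lp_state: FilterState,
    axis: str,
    preferred_direction: int,
    delta: float = 0.05,
) -> np.ndarray:
    """Advance the delay filter one frame and return one directional map.

    Use :func:`three_arm_correlate` with an externally advanced delay field
    when several directions share one filter (the usual case inside the
    full model — all four directions of a channel see the same delayed
    signal).
    """
    delayed = low_pass_step(x, lp_state)
    return three_arm_correlate(x, delayed, axis, preferred_direction, delta)


def pool_nondirectional_three_arm(
    left: np.ndarray,
    right: np.ndarray,
    up: np.ndarray,
    down: np.ndarray,
    params: ThreeArmParams,
    channel: str = "OFF",
) -> MotionField:
    """Pool four directional maps into one nondirectional motion field.

    Per axis the larger of the two opposed outputs wins at every site; the
    two axis winners are summed. With the adaptive threshold enabled, each
    axis first zeroes every output below ``threshold_fraction`` times that
    axis's field-wide maximum for the current frame (degenerate all-zero
    axes pass through unchanged).
    """
    maps = [np.asarray(m, dtype=float) for m in (left, right, up, down)]
    if len({m.shape for m in maps}) != 1:
        raise ValueError("all four directional maps must share a shape")
    left, right, up, down = maps
    if params.adaptive_threshold_enabled:
        pairs = []
        for pair in ((left, right), (up, down)):
            axis_max = max(pair[0].max(), pair[1].max())
            thr = params.threshold_fraction * axis_max
            if axis_max > 0:
                pair = tuple(np.where(m >= thr, m, 0.0) for m in pair)
            pairs.append(pair)
        (left, right), (up, down) = pairs
    values = np.maximum(left, right) + np.maximum(up, down)
    return MotionField(values=values, channel=channel)
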