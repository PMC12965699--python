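"""Segmentation of model outputs and all evaluation metrics.

Every probed stage output is first segmented at a relative threshold
(50 % of the frame's maximum). Against the (subsampled) ground truth the
package then computes:

* the accumulated pixel-wise **F-measure** ``2TP / (2TP + FP + FN)``,
  where TP/FP/FN are accumulated over the whole presentation before the
  ratio is formed;
* the distance-based **average precision** ``TP'/(TP'+FP')`` for
  sub-resolution objects whose boundary ground truth is lost by
  subsampling: a detected pixel counts as TP' iff its Euclidean distance
  to the ground-truth center does not exceed a threshold;
* **temporal alignment**: because the correlator delays shift responses
  several frames behind the stimulus, each stage is scored against ground
  truth shifted k frames into the past and the best lag is the argmax;
* frame-level **detection/false-alarm rate** pairs (D_R, F_A) and
  (P_d, F_a) for single-object video benchmarks, traced into curves by
  sweeping the segmentation threshold fraction.

All accumulators exclude an initial burn-in of ``ceil(5 * tau_LP1 / dh)``
frames so filter transients from the zero initial state never contaminate
the counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .stimuli import GroundTruth

__all__ = [
    "ConfusionAccumulator",
    "DistanceAccumulator",
    "DetectionRates",
    "AlignmentResult",
    "segment",
    "f_measure",
    "distance_threshold_limit",
    "transient_frames",
    "evaluate_f_measure",
    "precision_at_threshold",
    "average_precision",
    "alignment_sweep",
    "align_stages",
    "rist_rates",
    "ir_rates",
]

logger = logging.getLogger(__name__)

#: outputs whose maximum does not exceed this are treated as all-background
FLOOR_EPSILON = 1e-12


def segment(output: np.ndarray, fraction: float = 0.5,
            floor_epsilon: float = FLOOR_EPSILON,
            baseline: float = 0.0) -> np.ndarray:
    """Threshold an output matrix at ``fraction`` of its maximum value.

    Returns a boolean foreground mask; a (near-)zero matrix segments to
    all background. For outputs with a nonzero resting level (the sigmoid
    readout of the lobula module never reaches 0), pass the resting value
    as ``baseline``: thresholding then acts on the deviation from rest,
    which coincides with the plain rule whenever responses dominate the
    resting level and stays well defined when they do not.
    """
    out = np.asarray(output, dtype=float) - baseline
    peak = out.max() if out.size else 0.0
    if peak <= floor_epsilon:
        return np.zeros_like(out, dtype=bool)
    return out >= fraction * peak


def distance_threshold_limit(speed_px_s: float, lag_frames: int,
                             dh: float) -> float:
    """Displacement ``V * m * dh`` of a detection behind its ground truth.

    An object moving at ``speed_px_s`` whose response is aligned ``m``
    frames late sits this many raw pixels behind the current ground-truth
    location; distance thresholds for the precision plot should not
    exceed it.
    """
    return speed_px_s * lag_frames * dh


def transient_frames(dh: float, tau_lp1: float = 0.050) -> int:
    """Burn-in length: ceil(5 * tau_LP1 / dh) frames."""
    return math.ceil(5.0 * tau_lp1 / dh)


# ---------------------------------------------------------------------------
# Boundary (F-measure) evaluation
# ---------------------------------------------------------------------------

@dataclass
class ConfusionAccumulator:
    """Running TP/FP/FN counts accumulated over a presentation."""

    TP: int = 0
    FP: int = 0
    FN: int = 0

    def update(self, detected: np.ndarray, gt_mask: np.ndarray) -> None:
        detected = np.asarray(detected, dtype=bool)
        gt_mask = np.asarray(gt_mask, dtype=bool)
        self.TP += int(np.sum(detected & gt_mask))
        self.FP += int(np.sum(detected & ~gt_mask))
        self.FN += int(np.sum(~detected & gt_mask))


def f_measure(acc: ConfusionAccumulator) -> float:
    """Accumulated-counts F-measure ``2TP / (2TP + FP + FN)``.

    Undefined when there were neither objects nor detections; returns 0
    by convention (logged).
    """
    denom = 2 * acc.TP + acc.FP + acc.FN
    if denom == 0:
        logger.info("f_measure undefined (no objects, no detections); "
                    "returning 0 by convention")
        return 0.0
    return 2.0 * acc.TP / denom


def evaluate_f_measure(
    outputs: list[np.ndarray],
    gt: GroundTruth,
    lag: int = 0,
    burn_in: int = 0,
    threshold_fraction: float = 0.5,
    start_frame: int | None = None,
    baseline: float = 0.0,
) -> float:
    """Accumulated F-measure of segmented outputs against lagged ground truth.

    Frame ``t`` of the output is scored against ground-truth frame
    ``t - lag``. Scoring starts at ``max(burn_in + lag, start_frame)``
    so that filter transients and undefined lagged frames are excluded.
    """
    acc = ConfusionAccumulator()
    t0 = max(burn_in + lag, start_frame if start_frame is not None else 0)
    for t in range(t0, len(outputs)):
        acc.update(segment(outputs[t], threshold_fraction, baseline=baseline),
                   gt.masks[t - lag])
    return f_measure(acc)


# ---------------------------------------------------------------------------
# Distance-based (precision-plot) evaluation
# ---------------------------------------------------------------------------

@dataclass
class DistanceAccumulator:
    """Running TP'/FP' counts for the distance-thresholded precision."""

    TP: int = 0
    FP: int = 0


def precision_at_threshold(
    detections: np.ndarray,
    gt_center: tuple[float, float],
    dist_threshold: float,
    acc: DistanceAccumulator,
    pixel_pitch: float = 1.0,
) -> DistanceAccumulator:
    """Classify each detected pixel by Euclidean distance to the center.

    A pixel at lattice coordinates (r, c) is TP' iff
    ``hypot(r - center_row, c - center_col) * pixel_pitch`` is **not
    greater** than ``dist_threshold``; otherwise FP'. ``pixel_pitch``
    converts lattice distances to raw pixels (delta_phi for subsampled
    stimuli).
    """
    det = np.asarray(detections, dtype=bool)
    if not det.any():
        return acc
    rows, cols = np.nonzero(det)
    d = np.hypot(rows - gt_center[0], cols - gt_center[1]) * pixel_pitch
    within = d <= dist_threshold
    acc.TP += int(np.sum(within))
    acc.FP += int(np.sum(~within))
    return acc


def average_precision(
    outputs: list[np.ndarray],
    gt: GroundTruth,
    dist_threshold: float,
    lag: int = 0,
    burn_in: int = 0,
    threshold_fraction: float = 0.5,
    baseline: float = 0.0,
) -> float:
    """Accumulated precision' of segmented outputs at a distance threshold.

    Output frame ``t`` is scored against the ground-truth center at frame
    ``t - lag``; frames whose (subsampled) ground truth is lost — absent
    object or empty mask — are skipped. Distances are measured in raw
    pixels (lattice distance times the ground-truth stride). Returns 0 and
    logs if no pixel was ever detected.
    """
    acc = DistanceAccumulator()
    for t in range(burn_in + lag, len(outputs)):
        gtf = t - lag
        if not gt.present[gtf] or not gt.masks[gtf].any():
            continue
        center = tuple(gt.centers[gtf])
        precision_at_threshold(
            segment(outputs[t], threshold_fraction, baseline=baseline),
            center, dist_threshold, acc, pixel_pitch=gt.stride)
    total = acc.TP + acc.FP
    if total == 0:
        logger.warning("average_precision undefined (no detections); "
                       "returning 0 by convention")
        return 0.0
    return acc.TP / total


# ---------------------------------------------------------------------------
# Temporal alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    """Lag-vs-score curves and best lags for the probed stages."""

    lags: np.ndarray
    curves: dict[str, np.ndarray] = field(default_factory=dict)
    best: dict[str, int] = field(default_factory=dict)


def alignment_sweep(
    outputs: list[np.ndarray],
    gt: GroundTruth,
    max_lag: int = 8,
    burn_in: int = 0,
    threshold_fraction: float = 0.5,
    baseline: float = 0.0,
) -> tuple[int, np.ndarray]:
    """Score one output sequence against ground truth k frames in the past.

    For k = 0..max_lag, the accumulated F-measure is computed over the
    same set of response frames (``burn_in + max_lag`` onward, so every
    lag sees identical outputs); returns ``(argmax_k, scores)`` with ties
    broken toward smaller k.
    """
    if len(outputs) <= burn_in + max_lag:
        raise ValueError("sequence shorter than max_lag plus burn-in")
    scores = np.array([
        evaluate_f_measure(outputs, gt, lag=k, burn_in=burn_in,
                           threshold_fraction=threshold_fraction,
                           start_frame=burn_in + max_lag, baseline=baseline)
        for k in range(max_lag + 1)
    ])
    return int(np.argmax(scores)), scores


def align_stages(
    stage_outputs: dict[str, list[np.ndarray]],
    gt: GroundTruth,
    max_lag: int = 8,
    burn_in: int = 0,
    baselines: dict[str, float] | None = None,
) -> AlignmentResult:
    """Run :func:`alignment_sweep` for each named stage."""
    result = AlignmentResult(lags=np.arange(max_lag + 1))
    baselines = baselines or {}
    for name, outputs in stage_outputs.items():
        best, scores = alignment_sweep(outputs, gt, max_lag, burn_in,
                                       baseline=baselines.get(name, 0.0))
        result.curves[name] = scores
        result.best[name] = best
    return result


# ---------------------------------------------------------------------------
# Video-benchmark detection/false-alarm rates
# ---------------------------------------------------------------------------

@dataclass
class DetectionRates:
    """Detection-rate / false-alarm-rate pair at one segmentation threshold.

    ``detection_rate`` is N_TD/N_Frame where a frame counts one true
    detection if any detected pixel lies within the pixel tolerance of the
    ground-truth center (frame-level convention, so the rate lies in
    [0, 1]). ``false_alarm_rate`` is N_FD/N_Frame (false pixels per frame)
    for the D_R/F_A variant or N_FD/N_P for the P_d/F_a variant, with N_P
    the pixel count of a single frame.
    """

    threshold_fraction: float
    n_frames: int
    n_true_detections: int
    n_false_detections: int
    n_pixels: int
    detection_rate: float
    false_alarm_rate: float


def _rate_curve(
    outputs: list[np.ndarray],
    gt_centers: np.ndarray,
    pixel_tolerance: float,
    threshold_sweep: np.ndarray,
    burn_in: int,
    per_pixel_denominator: bool,
) -> list[DetectionRates]:
    curve = []
    n_pixels = int(np.asarray(outputs[0]).size)
    for frac in threshold_sweep:
        n_td = 0
        n_fd = 0
        n_frames = 0
        for t in range(burn_in, len(outputs)):
            center = gt_centers[t]
            if np.any(np.isnan(center)):
                continue
            n_frames += 1
            det = segment(outputs[t], float(frac))
            if not det.any():
                continue
            rows, cols = np.nonzero(det)
            d = np.hypot(rows - center[0], cols - center[1])
            true_px = d <= pixel_tolerance
            if true_px.any():
                n_td += 1
            n_fd += int(np.sum(~true_px))
        denom_fa = n_pixels if per_pixel_denominator else max(n_frames, 1)
        curve.append(DetectionRates(
            threshold_fraction=float(frac),
            n_frames=n_frames,
            n_true_detections=n_td,
            n_false_detections=n_fd,
            n_pixels=n_pixels,
            detection_rate=n_td / max(n_frames, 1),
            false_alarm_rate=n_fd / denom_fa,
        ))
    return curve


def rist_rates(
    outputs: list[np.ndarray],
    gt_centers: np.ndarray,
    pixel_tolerance: float = 5.0,
    threshold_sweep: np.ndarray | None = None,
    burn_in: int = 0,
) -> list[DetectionRates]:
    """D_R versus F_A curve for a single-object sequence.

    A detected pixel is true if its distance to the ground-truth center is
    not greater than ``pixel_tolerance`` (default 5 px). N_TD counts
    frames with at least one true pixel; N_FD accumulates false pixels;
    F_A = N_FD / N_Frame. The curve is traced by sweeping the
    segmentation threshold fraction (default 0.5..0.95).
    """
    if threshold_sweep is None:
        threshold_sweep = np.linspace(0.5, 0.95, 10)
    return _rate_curve(outputs, np.asarray(gt_centers, dtype=float),
                       pixel_tolerance, np.asarray(threshold_sweep),
                       burn_in, per_pixel_denominator=False)


def ir_rates(
    outputs: list[np.ndarray],
    gt_centers: np.ndarray,
    pixel_tolerance: float = 5.0,
    threshold_sweep: np.ndarray | None = None,
    burn_in: int = 0,
) -> list[DetectionRates]:
    """P_d versus F_a curve: as :func:`rist_rates` but F_a = N_FD / N_P.

    N_P is the pixel count of one frame; the accompanying ``n_frames``
    field records the accumulation length so the scale is explicit.
    """
    if threshold_sweep is None:
        threshold_sweep = np.linspace(0.5, 0.95, 10)
    return _rate_curve(outputs, np.asarray(gt_centers, dtype=float),
                       pixel_tolerance, np.asarray(threshold_sweep),
                       burn_in, per_pixel_denominator=True)
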