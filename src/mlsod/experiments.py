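"""Reusable experiment protocols built on the library surface.

These helpers wire the canonical stimulus (a small square object drifting
over a seeded procedural background), the retinal preprocessing, the
detector pipelines and the metrics into single calls, so tuning curves
and robustness comparisons can be reproduced in a few lines. They exist
for convenience only; everything here goes through the public module API.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detector import (
    LobulaParams,
    ModelParams,
    StageOutputs,
    run_estmd_pure,
    run_ml_sod,
)
from .metrics import alignment_sweep, evaluate_f_measure, transient_frames
from .stimuli import (
    BackgroundSpec,
    FlickerSpec,
    FrameSequence,
    GroundTruth,
    HighContrastObjectSpec,
    ObjectSpec,
    downsample_ground_truth,
    generate_sequence,
    retina_preprocess,
)

__all__ = [
    "DEFAULT_LAG",
    "StimulusProtocol",
    "make_retina_stimulus",
    "centered_object",
    "centered_high_contrast",
    "stage_lists",
    "stage_baselines",
    "stage2_f_measure",
    "estmd_f_measure",
    "size_tuning_curve",
    "speed_tuning_curve",
    "measure_alignment",
]

#: temporal alignment lag (frames) applied to stages 2 and 3 throughout
DEFAULT_LAG = 4


@dataclass
class StimulusProtocol:
    """The canonical artificial-stimulus conditions.

    A square object drifts leftward at constant speed over a seeded
    procedural texture; frames are blurred (12x12 Gaussian, sigma 3.5)
    and subsampled at stride 6 (delta_phi = 6 px); the ground truth is
    subsampled only. Frame rate 100 Hz (dh = 10 ms).
    """

    frame_shape: tuple[int, int] = (384, 512)
    n_frames: int = 100
    dt: float = 0.010
    seed: int = 0
    stride: int = 6
    kernel_size: int = 12
    sigma: float = 3.5
    background_velocity: float = 0.0
    margin: int = 40


def make_retina_stimulus(
    obj: ObjectSpec | HighContrastObjectSpec,
    protocol: StimulusProtocol | None = None,
    flicker: FlickerSpec | None = None,
) -> tuple[FrameSequence, GroundTruth]:
    """Generate a sequence under the protocol and preprocess to the retina.

    Returns the retina-lattice frame sequence and the stride-subsampled
    ground truth.
    """
    protocol = protocol or StimulusProtocol()
    bg = BackgroundSpec(
        velocity=protocol.background_velocity,
        seed=protocol.seed,
        shape=protocol.frame_shape,
    )
    seq, gt = generate_sequence(obj, bg, flicker=flicker,
                                n_frames=protocol.n_frames, dt=protocol.dt)
    retina = retina_preprocess(seq, kernel_size=protocol.kernel_size,
                               sigma=protocol.sigma, stride=protocol.stride)
    gt_down = downsample_ground_truth(gt, stride=protocol.stride)
    return retina, gt_down


def centered_object(
    size_px: int,
    speed_px_s: float,
    protocol: StimulusProtocol,
    luminance: float = 0.0,
) -> ObjectSpec:
    """Object starting near the right edge, drifting leftward.

    The start column leaves room for the full traversal where the frame
    allows it; the object may legitimately exit the frame for long/fast
    runs, after which its ground truth is absent.
    """
    H, W = protocol.frame_shape
    start = (H // 2 - size_px // 2,
             W - protocol.margin - size_px)
    return ObjectSpec(size_px=size_px, luminance=luminance,
                      speed_px_s=speed_px_s, direction=(0.0, -1.0),
                      start_position=start)


def centered_high_contrast(
    core_size: int,
    border_size: int,
    speed_px_s: float,
    protocol: StimulusProtocol,
    core_luminance: float = 0.0,
    border_luminance: float = 1.0,
) -> HighContrastObjectSpec:
    H, W = protocol.frame_shape
    start = (H // 2 - border_size // 2,
             W - protocol.margin - border_size)
    return HighContrastObjectSpec(
        core_size=core_size, border_size=border_size,
        core_luminance=core_luminance, border_luminance=border_luminance,
        speed_px_s=speed_px_s, direction=(0.0, -1.0), start_position=start)


def stage_lists(outputs: list[StageOutputs]) -> dict[str, list[np.ndarray]]:
    """Re-group per-frame stage outputs into per-stage frame lists."""
    return {
        "stage1": [o.stage1 for o in outputs],
        "stage2": [o.stage2 for o in outputs],
        "stage3": [o.stage3 for o in outputs],
    }


def stage_baselines(lob: LobulaParams | None = None) -> dict[str, float]:
    """Segmentation baselines per stage: stage 3 rests at the sigmoid floor."""
    lob = lob or LobulaParams()
    return {"stage1": 0.0, "stage2": 0.0, "stage3": lob.resting_output}


def stage2_f_measure(
    retina: FrameSequence,
    gt: GroundTruth,
    params: ModelParams | None = None,
    lob: LobulaParams | None = None,
    lag: int = DEFAULT_LAG,
    stage: str = "stage2",
) -> float:
    """Accumulated F-measure of one ml-SOD stage at the alignment lag."""
    outputs = run_ml_sod(retina, params, lob)
    burn_in = transient_frames(retina.dt)
    stages = stage_lists(outputs)
    baseline = stage_baselines(lob)[stage]
    return evaluate_f_measure(stages[stage], gt, lag=lag, burn_in=burn_in,
                              baseline=baseline)


def estmd_f_measure(
    retina: FrameSequence,
    gt: GroundTruth,
    params: ModelParams | None = None,
    lag: int = DEFAULT_LAG,
) -> float:
    """Accumulated F-measure of the ESTMD (pure) baseline at the lag."""
    outputs = run_estmd_pure(retina, params)
    burn_in = transient_frames(retina.dt)
    return evaluate_f_measure(outputs, gt, lag=lag, burn_in=burn_in)


def size_tuning_curve(
    sizes: list[int],
    speed_px_s: float = 200.0,
    protocol: StimulusProtocol | None = None,
    params: ModelParams | None = None,
    lob: LobulaParams | None = None,
    stage: str = "stage2",
    luminance: float = 0.0,
    lag: int = DEFAULT_LAG,
) -> np.ndarray:
    """F-measure of one stage as a function of object size."""
    protocol = protocol or StimulusProtocol()
    scores = []
    for s in sizes:
        obj = centered_object(s, speed_px_s, protocol, luminance)
        retina, gt = make_retina_stimulus(obj, protocol)
        scores.append(stage2_f_measure(retina, gt, params, lob,
                                       lag=lag, stage=stage))
    return np.asarray(scores)


def speed_tuning_curve(
    speeds: list[float],
    size_px: int = 6,
    protocol: StimulusProtocol | None = None,
    params: ModelParams | None = None,
    lob: LobulaParams | None = None,
    stage: str = "stage2",
    luminance: float = 0.0,
    lag: int = DEFAULT_LAG,
) -> np.ndarray:
    """F-measure of one stage as a function of object speed."""
    protocol = protocol or StimulusProtocol()
    scores = []
    for v in speeds:
        obj = centered_object(size_px, v, protocol, luminance)
        retina, gt = make_retina_stimulus(obj, protocol)
        scores.append(stage2_f_measure(retina, gt, params, lob,
                                       lag=lag, stage=stage))
    return np.asarray(scores)


def measure_alignment(
    retina: FrameSequence,
    gt: GroundTruth,
    params: ModelParams | None = None,
    lob: LobulaParams | None = None,
    max_lag: int = 8,
) -> dict[str, tuple[int, np.ndarray]]:
    """Best lag and lag-vs-F curve per stage for one stimulus run."""
    outputs = run_ml_sod(retina, params, lob)
    burn_in = transient_frames(retina.dt)
    baselines = stage_baselines(lob)
    return {
        name: alignment_sweep(frames, gt, max_lag=max_lag, burn_in=burn_in,
                              baseline=baselines[name])
        for name, frames in stage_lists(outputs).items()
    }
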