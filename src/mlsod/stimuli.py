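"""Synthetic stimulus generation and retinal preprocessing.

Stimuli emulate the classic small-target paradigm: a small square object of
adjustable size, luminance and velocity translating over a (optionally
moving) textured background, with exact per-frame ground truth. Variants
add a high-contrast core+border object and synchronously flickering
distractor dots. A procedural 1/f-textured background stands in for a
natural image so arbitrarily long, seeded sequences can be produced with no
external data.

Retinal preprocessing models the optics of a fly compound eye: a Gaussian
blur (photoreceptor acceptance angle) followed by subsampling on a regular
lattice (interommatidial spacing delta_phi = the subsampling stride).
Ground truth is only subsampled, never blurred, so the ground truth of an
object smaller than the lattice spacing can fall between retained pixels
and vanish for some frames — a real property of the paradigm that the
evaluation code must confront, not a bug.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ObjectSpec",
    "HighContrastObjectSpec",
    "FlickerSpec",
    "BackgroundSpec",
    "FrameSequence",
    "GroundTruth",
    "generate_sequence",
    "weber_contrast",
    "retina_preprocess",
    "downsample_ground_truth",
    "make_procedural_background",
    "gaussian_kernel_1d",
    "blur_fwhm",
    "write_sequence",
    "write_ground_truth",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class ObjectSpec:
    """A plain square object.

    ``start_position`` is the (row, col) of the object's top-left corner at
    t = 0; the drawn footprint is ``size_px`` x ``size_px``. ``direction``
    is a unit vector along an image axis; the velocity in px/s is
    ``speed_px_s * direction``.
    """

    size_px: int = 6
    luminance: float = 0.0
    speed_px_s: float = 200.0
    direction: tuple[float, float] = (0.0, -1.0)  # (drow, dcol); default leftward
    start_position: tuple[float, float] = (100.0, 400.0)

    def __post_init__(self) -> None:
        if self.size_px < 1:
            raise ValueError("object size must be >= 1 pixel")
        if not 0.0 <= self.luminance <= 1.0:
            raise ValueError("object luminance must lie in [0, 1]")

    @property
    def footprint(self) -> int:
        return self.size_px


@dataclass
class HighContrastObjectSpec:
    """Concentric core+border object: a d x d core inside a D x D border."""

    core_size: int = 10
    border_size: int = 40
    core_luminance: float = 0.0
    border_luminance: float = 1.0
    speed_px_s: float = 200.0
    direction: tuple[float, float] = (0.0, -1.0)
    start_position: tuple[float, float] = (100.0, 400.0)

    def __post_init__(self) -> None:
        if self.border_size < self.core_size:
            raise ValueError("border size D must be >= core size d")
        for lum in (self.core_luminance, self.border_luminance):
            if not 0.0 <= lum <= 1.0:
                raise ValueError("luminances must lie in [0, 1]")

    @property
    def footprint(self) -> int:
        return self.border_size


@dataclass
class FlickerSpec:
    """Synchronously flickering square dots scattered over the background.

    All dots share one phase: they start black and switch between black
    (0.0) and white (1.0) at every half period 1/(2*frequency), rounded to
    the nearest whole number of frames.
    """

    n_dots: int = 25
    dot_size: int = 6
    frequency: float = 50.0
    seed: int = 0


@dataclass
class BackgroundSpec:
    """Textured background, either procedural or loaded from file.

    The background translates rigidly at ``velocity`` px/s along the
    horizontal axis with periodic wrap-around.
    """

    velocity: float = 0.0
    seed: int = 0
    correlation_length: float = 50.0
    contrast: float = 0.8
    shape: tuple[int, int] = (675, 1024)  # (H, W) of the procedural texture
    image: np.ndarray | None = None  # optional explicit texture in [0, 1]


@dataclass
class FrameSequence:
    """Time-ordered stack of 2-D luminance frames in [0, 1]."""

    frames: np.ndarray  # (T, H, W) float
    dt: float
    resolution_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class GroundTruth:
    """Per-frame object masks, centers and presence flags.

    ``centers`` holds (row, col) of the object's geometric center rounded
    to the nearest pixel, NaN where the object does not overlap the frame.
    ``masks`` may be empty on frames where ``present`` is True once the
    ground truth has been subsampled below the object scale.
    """

    masks: np.ndarray  # (T, H, W) bool
    centers: np.ndarray  # (T, 2) float, NaN when absent
    present: np.ndarray  # (T,) bool: object overlaps the frame
    resolution_tag: str = "raw"
    stride: int = 1


# ---------------------------------------------------------------------------
# Background texture
# ---------------------------------------------------------------------------

def make_procedural_background(
    H: int,
    W: int,
    seed: int = 0,
    correlation_length: float = 50.0,
    contrast: float = 0.8,
) -> np.ndarray:
    """Generate a natural-image-like grayscale texture in [0, 1].

    White Gaussian noise is shaped in the Fourier domain with a 1/f
    amplitude falloff, ``A(f) = 1 / (f + 1/correlation_length)``, which
    concentrates power at low spatial frequencies the way natural scenes
    do. The field is then centered on 0.5 and scaled so that at
    ``contrast=1`` the values span the full [0, 1] range.
    """
    if H <= 0 or W <= 0:
        raise ValueError("background dimensions must be positive")
    if contrast == 0:
        return np.full((H, W), 0.5)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((H, W))
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    f = np.hypot(fy, fx)
    amplitude = 1.0 / (f + 1.0 / float(correlation_length))
    shaped = np.fft.ifft2(np.fft.fft2(noise) * amplitude).real
    shaped -= shaped.mean()
    peak = np.abs(shaped).max()
    if peak > 0:
        shaped /= peak
    return np.clip(0.5 + 0.5 * float(contrast) * shaped, 0.0, 1.0)


def _background_texture(background: BackgroundSpec, H: int, W: int) -> np.ndarray:
    if background.image is not None:
        tex = np.asarray(background.image, dtype=float)
        if tex.shape != (H, W):
            raise ValueError("explicit background image must match frame shape")
        if tex.min() < 0 or tex.max() > 1:
            raise ValueError("background texture values must lie in [0, 1]")
        return tex
    return make_procedural_background(
        H, W, background.seed, background.correlation_length, background.contrast
    )


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

def _flicker_layout(
    flicker: FlickerSpec, H: int, W: int
) -> np.ndarray:
    """Fixed (n_dots, 2) top-left corners, dots fully inside the frame."""
    rng = np.random.default_rng(flicker.seed)
    rows = rng.integers(0, H - flicker.dot_size + 1, size=flicker.n_dots)
    cols = rng.integers(0, W - flicker.dot_size + 1, size=flicker.n_dots)
    return np.stack([rows, cols], axis=1)


def flicker_value(flicker: FlickerSpec, frame_index: int, dt: float) -> float:
    """Dot luminance at a frame: starts black, toggles every half period."""
    half_period_frames = max(1, round(1.0 / (2.0 * flicker.frequency * dt)))
    return 1.0 if (frame_index // half_period_frames) % 2 else 0.0


def _paint_square(frame: np.ndarray, top: int, left: int, size: int,
                  value: float) -> tuple[slice, slice] | None:
    """Paint the in-frame part of a square; return the painted slices."""
    H, W = frame.shape
    r0, r1 = max(top, 0), min(top + size, H)
    c0, c1 = max(left, 0), min(left + size, W)
    if r0 >= r1 or c0 >= c1:
        return None
    sl = (slice(r0, r1), slice(c0, c1))
    frame[sl] = value
    return sl


def generate_sequence(
    obj: ObjectSpec | HighContrastObjectSpec,
    background: BackgroundSpec,
    flicker: FlickerSpec | None = None,
    n_frames: int = 100,
    dt: float = 0.010,
) -> tuple[FrameSequence, GroundTruth]:
    """Compose object (+ optional flicker dots) over a translating background.

    Per frame: the background is rolled by ``round(velocity * t)`` pixels
    (periodic wrap-around), flicker dots are painted on it, and the object
    is painted on top (border first, then core, for high-contrast objects).
    Subpixel object positions are rounded to the nearest pixel — objects
    are hard-edged squares, not anti-aliased. The ground-truth mask marks
    the object's pixels; for the high-contrast object that is the core
    footprint (the bright border is a contrast enhancer around the object,
    and the detector's response is core-sized, so boundary-level scoring
    against the full composite patch would be meaningless). The center is
    the geometric center of the masked footprint, rounded to the nearest
    pixel.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if background.image is not None:
        H, W = background.image.shape
    else:
        H, W = background.shape
    tex = _background_texture(background, H, W)
    size = obj.footprint
    if size > min(H, W):
        raise ValueError("object footprint larger than the frame")

    dot_layout = _flicker_layout(flicker, H, W) if flicker is not None else None

    frames = np.empty((n_frames, H, W), dtype=float)
    masks = np.zeros((n_frames, H, W), dtype=bool)
    centers = np.full((n_frames, 2), np.nan)
    present = np.zeros(n_frames, dtype=bool)

    vr = obj.speed_px_s * obj.direction[0]
    vc = obj.speed_px_s * obj.direction[1]
    r0, c0 = obj.start_position

    for t in range(n_frames):
        shift = int(round(background.velocity * t * dt))
        frame = np.roll(tex, shift, axis=1) if shift else tex.copy()

        if dot_layout is not None:
            val = flicker_value(flicker, t, dt)
            for dr, dc in dot_layout:
                frame[dr:dr + flicker.dot_size, dc:dc + flicker.dot_size] = val

        top = int(round(r0 + vr * t * dt))
        left = int(round(c0 + vc * t * dt))
        if isinstance(obj, HighContrastObjectSpec):
            # border drawn first, core over it; ground truth tracks the core
            _paint_square(frame, top, left, obj.border_size,
                          obj.border_luminance)
            off = (obj.border_size - obj.core_size) // 2
            sl = _paint_square(frame, top + off, left + off, obj.core_size,
                               obj.core_luminance)
            gt_top, gt_left, gt_size = top + off, left + off, obj.core_size
        else:
            sl = _paint_square(frame, top, left, obj.size_px, obj.luminance)
            gt_top, gt_left, gt_size = top, left, obj.size_px

        if sl is not None:
            masks[t][sl] = True
            centers[t] = (round(gt_top + (gt_size - 1) / 2.0),
                          round(gt_left + (gt_size - 1) / 2.0))
            present[t] = True
        frames[t] = frame

    seq = FrameSequence(frames=frames, dt=dt, resolution_tag="raw")
    gt = GroundTruth(masks=masks, centers=centers, present=present,
                     resolution_tag="raw", stride=1)
    return seq, gt


def weber_contrast(I_C: float, I_S: float) -> float:
    """Weber contrast of a core of luminance I_C inside a border I_S.

    Defined as (I_S - I_C) / I_S: contrast grows as the core darkens at
    fixed bright surround.
    """
    if I_S == 0:
        raise ValueError("border luminance I_S must be nonzero")
    return (I_S - I_C) / I_S


# ---------------------------------------------------------------------------
# Retinal preprocessing
# ---------------------------------------------------------------------------

def gaussian_kernel_1d(kernel_size: int, sigma: float) -> np.ndarray:
    """Unit-sum 1-D Gaussian sampled on a length-``kernel_size`` window.

    Sample points are symmetric about the window center (half-integer
    offsets for even sizes), matching the construction used by MATLAB's
    ``fspecial('gaussian')`` — the separable factors of that 2-D kernel.
    """
    u = np.arange(kernel_size) - (kernel_size - 1) / 2.0
    k = np.exp(-(u ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def blur_fwhm(sigma: float) -> float:
    """Full width at half maximum of a Gaussian blur, 2*sqrt(2*ln2)*sigma.

    This is the modeled photoreceptor acceptance angle in pixels.
    """
    return 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma


def retina_preprocess(
    seq: FrameSequence,
    kernel_size: int = 12,
    sigma: float = 3.5,
    stride: int = 6,
) -> FrameSequence:
    """Gaussian-blur then subsample each frame onto the retina lattice.

    The blur kernel emulates the photoreceptor acceptance angle (FWHM
    ~2.35*sigma pixels); retaining one pixel every ``stride`` pixels along
    both axes (starting at index 0) sets the interommatidial spacing
    delta_phi = ``stride`` raw pixels. Borders use replicate padding so a
    uniform frame stays uniform.
    """
    if seq.resolution_tag != "raw":
        raise ValueError("retina_preprocess expects a raw-resolution sequence")
    H, W = seq.shape
    if H < kernel_size or W < kernel_size:
        raise ValueError("frame smaller than the blur kernel")
    k = gaussian_kernel_1d(kernel_size, sigma)
    blurred = ndimage.correlate1d(seq.frames, k, axis=1, mode="nearest")
    blurred = ndimage.correlate1d(blurred, k, axis=2, mode="nearest")
    return FrameSequence(frames=blurred[:, ::stride, ::stride].copy(),
                         dt=seq.dt, resolution_tag="retina")


def downsample_ground_truth(gt: GroundTruth, stride: int = 6) -> GroundTruth:
    """Subsample ground truth with the same offsets/stride as the frames.

    Masks are *not* blurred before subsampling, so an object smaller than
    the stride can fall entirely between retained pixels and yield an empty
    mask on some frames; this loss is intrinsic to the paradigm and is
    deliberately reproduced. Centers map by integer division.
    """
    if gt.resolution_tag != "raw":
        raise ValueError("ground truth already downsampled")
    masks = gt.masks[:, ::stride, ::stride]
    centers = np.where(np.isnan(gt.centers), np.nan, gt.centers // stride)
    return GroundTruth(masks=masks, centers=centers, present=gt.present.copy(),
                       resolution_tag="retina", stride=stride)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_sequence(seq: FrameSequence, out_dir: str | Path) -> None:
    """Write frames as zero-padded 16-bit grayscale PNGs."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        img = np.clip(frame, 0, 1)
        iio.imwrite(out / f"frame_{i:06d}.png",
                    (img * 65535).round().astype(np.uint16))


def write_ground_truth(gt: GroundTruth, out_dir: str | Path) -> None:
    """Write masks as PNGs and centers as a CSV."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, mask in enumerate(gt.masks):
        iio.imwrite(out / f"mask_{i:06d}.png",
                    (mask.astype(np.uint8) * 255))
    with open(out / "centers.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "center_row", "center_col", "present"])
        for i in range(gt.masks.shape[0]):
            r, c = gt.centers[i]
            writer.writerow([
                i,
                "" if np.isnan(r) else int(r),
                "" if np.isnan(c) else int(c),
                int(gt.present[i]),
            ])
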