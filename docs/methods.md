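# Methods

## Model and assumptions

The detector treats a small moving object as a spatiotemporal coincidence
of its two edges. A dark object crossing a retinotopic location first
darkens it (leading edge → OFF transient, and OFF motion in the
correlator array) and, after the passage time S/V, brightens it again
(trailing edge → ON transient). Multiplying the *delayed* nondirectional
OFF motion with the *undelayed* ON luminance at the same location yields a
response only where both events occurred in the right order and within
the delay window τ — hence the matching rule S ≈ V·τ for the preferred
stimulus, and complete blindness to static scenes (no motion → stage 2 is
identically zero, stage 3 rests). The light-object pathway swaps
polarities; the two pathways are always run and evaluated separately,
never summed.

Visual motion is nondirectional by construction: the signed outputs of
correlators along both image axes are full-wave rectified and summed
(two-arm), or the larger of each axis's two opposed detectors is taken
and the axis winners summed (three-arm). Direction of object motion is
therefore irrelevant to detection.

Modeling assumptions worth keeping in mind:

* Photoreceptors are linear: luminance is the pixel value; there is no
  logarithmic transduction or adaptation stage.
* No center–surround antagonism and no fast-adaptation nonlinearity; the
  model is deliberately minimal, so elongated features orthogonal to the
  motion axis are not suppressed.
* Filters are first-order and spatially homogeneous; all states start at
  zero, and every metric excludes a burn-in of ceil(5·τ_LP1/Δh) frames
  (25 frames at Δh = 10 ms) so that the switch-on transient never enters
  the counts.

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ_HP | 30 ms | luminance high-pass (removes standing luminance) |
| τ_LP1 | 50 ms | correlator delay arm (both detector families) |
| τ_LP2 = τ | 30 ms | motion delay before feature combination; sets S = V·τ |
| Δφ | 6 px | lattice spacing for artificial stimuli (1 px for video) |
| blur | 12×12 px, σ = 3.5 px | photoreceptor acceptance; FWHM = 2√(2 ln 2)·σ ≈ 8.2 px |
| RF | 3Δφ×3Δφ, σ = 0.5Δφ | lobula receptive field (σ scales with size in sweeps) |
| δ | 0.05 (0.01 in three-arm comparisons) | divisive-arm guard constant |
| τ_m, E_L, R | 5 ms, −50 mV, 1 | lobula membrane |
| w_ext, E_ext | 0.1, 0 mV | synaptic weight and reversal potential |
| θ, β | −40 mV, 0.5 mV | sigmoid half-activation and steepness |
| Δh | 10 ms (1/f_video for video input) | frame period |

**Conductance gain.** Stage-2 values are products of four small filtered
quantities and come out of order 10⁻⁴ for a mid-contrast stimulus on the
retina lattice, while the membrane equation needs conductances of order 1
for `w_ext·g·(E_ext−V)` to move the potential across the sigmoid's
sensitive range around θ. The receptive-field kernel is normalized to
unit sum and scaled by an explicit gain (default 10⁵) bridging those
scales. Stage-2 metrics are exactly invariant to this gain because the
segmentation threshold is relative; stage-3 segmentation depends on it
only through the sigmoid's curvature.

## Synthetic stimuli

The generator emulates the classic small-target paradigm: a hard-edged
square object (subpixel positions rounded to the nearest pixel) drifting
at constant velocity over a textured background that may itself translate
rigidly (periodic wrap-around, per-frame offsets rounded to integers).
Variants add a concentric core+border high-contrast object (border drawn
first, core over it; local contrast quantified as Weber contrast
C = (I_S − I_C)/I_S) and synchronously flickering dots (fixed seeded
positions, starting black, toggling every half period rounded to whole
frames, never drawn over the object).

The background is a seeded procedural texture: Fourier-shaped Gaussian
noise with amplitude 1/(f + 1/L), L = 50 px, centered on 0.5 and scaled
by a contrast parameter (default 0.8). This reproduces the 1/f amplitude
falloff of natural scenes and supports arbitrary sizes and exact
reproducibility. It does *not* reproduce the sharp high-contrast edges,
occlusions and semantic structure of photographs; in particular its
fine-scale local contrast is milder than a natural image's, so the
luminance-only ESTMD (pure) baseline degrades less here under fast
background motion than it does with natural imagery — the comparison
"ml-SOD ≥ ESTMD (pure)" still holds at every tested background velocity,
but as ≥ rather than ≫. Under flicker noise the separation is large in
either case. Passing tests on this generator demonstrate the model's
mechanics and relative robustness, not absolute performance on natural
video.

Retinal preprocessing blurs each frame with a separable 12×12 Gaussian
(σ = 3.5 px, samples at half-integer offsets as in the standard even-size
construction, replicate borders) and keeps every 6th pixel starting at
index 0. Ground truth is subsampled with the same offsets but *never*
blurred: an object smaller than the stride can fall entirely between
retained pixels and lose its ground truth on some frames. This loss is a
property of the paradigm; boundary-level F-measure is meaningless for
such objects, which is exactly why the distance-thresholded precision
plot exists.

**High-contrast object ground truth.** The mask marks the d×d core, not
the full D×D composite. The bright border is a contrast enhancer around
the object; the detector's response is core-sized, and scoring against
the full 40×40 patch would cap the F-measure near 0.04 for a correctly
localized detection, making the boundary metric uninformative.

## Evaluation

Outputs are segmented per frame at 50 % of the frame maximum. Stage 3 is
segmented on its deviation from the resting readout sigmoid((E_L−θ)/β)
≈ 2×10⁻⁹: the rule coincides with plain 50 %-of-max whenever responses
dominate rest and stays well defined on near-rest frames (where the raw
rule would mark the entire field foreground).

* **F-measure** 2TP/(2TP+FP+FN), with TP/FP/FN accumulated over the whole
  presentation before the ratio (an undefined 0/0 reports 0 and logs).
* **Average precision′** TP′/(TP′+FP′): a detected pixel is true iff its
  Euclidean distance to the ground-truth center is ≤ the threshold
  (lattice distances × Δφ, centers mapped by integer division); frames
  with lost ground truth are skipped. The threshold budget for
  lag-aligned evaluation is V·m·Δh (16 px at V = 400 px/s, m = 4).
* **Temporal alignment**: each stage is scored against ground truth k
  frames in the past, k = 0..8, over a common set of response frames;
  best lag = argmax, ties toward smaller k. The measured lag is m = 4 for
  stages 2 and 3 under canonical conditions and is applied as the fixed
  alignment rule elsewhere. Stage 1's lag is reported as measured rather
  than asserted (it is small, 0–1 frames under canonical conditions).
* **D_R/F_A and P_d/F_a** for single-object video: a detected pixel is
  true within 5 px of the center; a frame counts one true detection if it
  has any true pixel (so D_R ∈ [0, 1]); F_A divides accumulated false
  pixels by the frame count, F_a by the pixel count of one frame (the
  frame count is reported alongside to make the scale explicit). Curves
  are traced by sweeping the segmentation threshold fraction over
  0.5–0.95, under which both rates are nonincreasing.

## Numerical choices

* Filters use the exact exponential (zero-order-hold) discretization
  α = 1 − exp(−Δh/τ): unconditionally stable, exact for piecewise-
  constant input, valid at any frame rate (10 ms and 4.2 ms alike).
* The two-arm correlator output is assigned to the lower-index location
  of each pair (last row/column zero); the three-arm output to the center
  of each triple (borders zero). All four directional three-arm detectors
  of a channel share one delayed field, as do the two EMD axes.
* The lobula ODE is linear in V with rate (1 + w_ext·g)/τ_m; RK4 runs at
  1 ms substeps, and the substep count is raised whenever a very large
  conductance (possible with the three-arm δ-division and high gain)
  would leave RK4's stability region. Steady states match the analytic
  value E_L/(1 + w_ext·g) to 10⁻⁶.
* The adaptive three-arm threshold is applied per frame and per axis on
  the directional maps before max-pooling, at half the axis-wide maximum;
  an all-zero axis passes through unchanged.
* Degenerate metrics (no detections and no objects) report 0 and log.

## Design choices on genuinely open points

* **Background boundary handling**: periodic wrap-around, so arbitrarily
  long sequences exist at any background speed.
* **ESTMD (pure) delay arm**: the same τ_LP2 = 30 ms as the ml-SOD
  combination delay — the baseline shares every parameter value.
* **T4 vs T5 three-arm wiring**: identical algebra is applied per channel
  to its rectified signal; any ON/OFF structural asymmetry beyond arm
  mirroring is not modeled.
* **Tuning-curve probes**: with per-frame relative segmentation on a
  single static background, the F-measure expresses size/speed preference
  mainly through blob/mask geometry; the interior-maximum properties use
  F directly, while the τ-dependent peak *shifts* (the matching rule) are
  probed on the stage-2 peak response amplitude, where they express
  cleanly.
* **Receptive-field sweeps** scale σ with the kernel size (σ = size/6),
  preserving the default 3:0.5 ratio; growing the support at fixed
  σ = 0.5 lattice units would change nothing (the Gaussian dies inside
  3×3).

## Problem sizes

Desk-scale runs use 100-frame sequences on a 384×512-px background
(64×86 retina lattice); speed sweeps widen the frame to 384×768 so fast
objects stay in view through the scored window. These sizes keep every
experiment deterministic and fast while leaving dozens of post-transient
frames for metric accumulation.

## Known limitations

* Static or momentarily stopped objects are undetectable by design.
* No suppression of extended features orthogonal to the motion axis
  (no center–surround antagonism).
* The procedural background understates natural-scene clutter (above).
* Stage-3 absolute output levels depend on the conductance-gain operating
  point; only relative (within-frame) structure is interpreted.
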