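# mlsod — motion-luminance small object detection

Flying insects find small moving targets — prey, conspecifics — against
heavily cluttered scenes using eyes with very coarse spatial sampling.
`mlsod` implements a minimal fly-inspired model of that ability for
researchers in computational neuroscience and bio-inspired vision: it
detects a small moving object as a multiplicative coincidence between two
features that arrive at the same retinotopic location in sequence — the
**nondirectional visual motion** of the object's leading edge and, a delay
τ later, the **luminance transient** of its trailing edge in the
opposite-polarity channel.

The package contains:

* the full three-stage detector (ml-SOD) with either two-arm
  Hassenstein–Reichardt correlators or three-arm T4/T5-like detectors
  (`a·b/(c+δ)` with divisive null-side inhibition and an optional adaptive
  output threshold);
* the luminance-only baseline **ESTMD (pure)** — the same filters with the
  motion arm ablated — for controlled comparisons;
* a synthetic stimulus generator (square objects, high-contrast
  core+border objects, flicker-dot noise, moving 1/f procedural
  backgrounds) with exact per-frame ground truth, plus the retinal
  preprocessing of a compound eye (Gaussian blur + lattice subsampling);
* the evaluation stack: relative-threshold segmentation, accumulated
  F-measure, distance-thresholded precision plots, temporal alignment
  sweeps, and detection/false-alarm rate curves for video benchmarks.

## Model

Each input frame (luminance in [0, 1], sampling period Δh) is high-pass
filtered (τ_HP = 30 ms) and half-wave rectified into ON and OFF channels.
The dark-object pathway then computes, on the retina lattice:

* **Stage 1** — OFF visual motion, pooled nondirectionally:
  `M_OFF = |EMD_horizontal| + |EMD_vertical|`, each EMD correlating a
  delayed (LP₁, τ_LP1 = 50 ms) signal with its undelayed neighbor.
* **Stage 2** — feature combination:
  `S2 = LP₂(M_OFF) ⊙ L_ON`, with τ_LP2 = τ = 30 ms. Motion gating makes
  the model blind to anything static.
* **Stage 3** — a lobula module of nonspiking units: S2 is pooled by a
  3Δφ×3Δφ Gaussian receptive field into a conductance g driving
  `τ_m dV/dt = −V + E_L + R·w_ext·g·(E_ext − V)` (RK4, 1 ms substeps),
  read out as `1/(1+exp((θ−V)/β))`.

The light-object pathway is the polarity mirror (`LP₂(M_ON) ⊙ L_OFF`).
The preferred stimulus obeys the matching rule **S ≈ V·τ**: the time an
object of size S moving at V spends at one location must match the
combination delay.

## Worked example

Temporal alignment of the detector on the canonical stimulus — a 6×6 px
dark object at 200 px/s over a stationary textured background, 100 frames
at Δh = 10 ms:

```python
import numpy as np
from mlsod import (ObjectSpec, BackgroundSpec, generate_sequence,
                   retina_preprocess, downsample_ground_truth,
                   run_ml_sod, alignment_sweep, transient_frames)

obj = ObjectSpec(size_px=6, luminance=0.0, speed_px_s=200.0,
                 direction=(0.0, -1.0), start_position=(180.0, 460.0))
bg = BackgroundSpec(seed=1, shape=(384, 512))
seq, gt = generate_sequence(obj, bg, n_frames=100, dt=0.010)
retina = retina_preprocess(seq)          # 12x12 Gaussian blur, stride 6
gt6 = downsample_ground_truth(gt, 6)     # subsample only (no blur)
outputs = run_ml_sod(retina)             # two-arm EMDs, dark pathway
stage2 = [o.stage2 for o in outputs]
burn_in = transient_frames(retina.dt)    # 25 frames (5 * tau_LP1)
best, curve = alignment_sweep(stage2, gt6, max_lag=8, burn_in=burn_in)
print(f"retina lattice: {retina.shape}, delta_phi = 6 px")
print(f"stage-2 F-measure vs lag: {np.round(curve, 3)}")
print(f"best lag m = {best} frames ({best * retina.dt * 1e3:.0f} ms)")
```

prints

```
retina lattice: (64, 86), delta_phi = 6 px
stage-2 F-measure vs lag: [0.    0.    0.218 0.427 0.635 0.464 0.256 0.047 0.   ]
best lag m = 4 frames (40 ms)
```

The detector's response trails the stimulus: scoring frame *t* against the
ground truth of frame *t − k* peaks at **k = 4** — the correlator delays
(mostly LP₂) place the stage-2/3 response four frames behind the object.
All artificial-stimulus evaluations apply this alignment rule. The same
machinery shows hyperacute detection: a 3×3 px object — half the lattice
spacing Δφ = 6 px — is localized with average precision 1.0 at a distance
threshold of 2Δφ, because the pre-sampling blur spreads even sub-pixel
objects across several photoreceptors.

## Command line

```sh
mlsod synth --config cfg.yaml --out stim/          # frames + ground truth
mlsod run   --config cfg.yaml --input stim/frames --out run/
mlsod eval  --run-dir run/ --gt-dir stim/gt --metric alignment --out rep.json
mlsod sweep --config cfg.yaml --parameter size --grid 2,4,6,10 --out sizes.csv
```

Real video datasets are consumed as image directories with a
`manifest.yaml` giving the frame rate (`dt = 1/f_video`); they run at full
resolution (Δφ = 1 px, no preprocessing) and are scored with the
detection-rate/false-alarm-rate curves (`--metric rist` or `ir`).

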