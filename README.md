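# adpt — anti-drift animal pose tracking

`adpt` is a Python library (plus a thin `adpt` command-line tool) for
markerless animal pose estimation that is built, end to end, around one
failure mode: **tracking drift** — the sudden, noise-induced jumps of
estimated body keypoints that corrupt downstream gait analysis, behavior
classification and social-interaction studies. It provides:

- a **cascaded CNN–transformer network** that maps a video frame to four
  stride-8 head maps: per-keypoint confidence heatmaps, location-refinement
  offsets, a low-resolution semantic segmentation (LRSS) of the body, and
  body affinity fields (BAF);
- **identity-aware decoding** for multi-animal scenes: BAF vectors vote each
  body pixel to its instance center, LRSS labels that center, and heatmap
  peaks inherit the resulting identity map — followed by a temporal pass
  that repairs identity swaps using motion continuity;
- **mix-up synthesis** of two-animal labeled frames from single-animal
  material by hard background-subtraction compositing;
- a quantitative **anti-drift evaluation suite** (drift and miss fractions,
  identity change rate, PCK, OKS/mAP, RMSE);
- a deterministic **synthetic scene generator** (articulated stick-figure
  animals with per-animal textures) so every code path is trainable and
  testable on one CPU with no external data.

The network is implemented on a compact numpy reverse-mode autodiff core
(`adpt.nn`) — convolutions, transposed convolutions, max-pooling,
multi-head attention, layer norm, AdamW — so the package has no deep
learning framework dependency.

## The model in brief

For K keypoints, a frame (resized by `global_scale`) is encoded at stride
*s* = 8. The training targets are:

- **Heatmaps** `H_k(p) = max_i exp(-||p - y_k,i / s||² / 2σ²)` with the cell
  nearest each keypoint set to exactly 1, so the peak cell plus its offset
  inverts the encoding exactly.
- **Location refinement** stores `(x - s·p_x, y - s·p_y)` at cells within a
  radius of the keypoint; decoding reads `y = s·argmax + locref(argmax)`.
- **LRSS** `M(p) = identity` if `p` lies on a rasterized limb segment
  between skeleton keypoints of that instance, else 0 — a coarse body
  segmentation that doubles as an identity classifier
  (`identity = argmax_c Σ_p P_c(p)` over the per-identity channels).
- **BAF** `B(p) = p - center` on body pixels, `(0, 0)` elsewhere, so
  `p - B(p)` recovers each pixel's instance center.

Training follows a warm-up/cosine learning-rate schedule (1e-5 → 1e-3 →
1e-5), batch 8, AdamW with weight decay 1e-4, RMSE losses for the
regression heads and sparse categorical cross-entropy for LRSS, with early
stopping after a 30-epoch plateau.

Drift is quantified per keypoint as
`drift@α = (1/F) Σ_i δ(||y_i − y_{i−1}|| > α)` (α = 50 px for mice),
misses as the fraction of frames with confidence ≤ 0.2, and identity
swaps as the per-identity center change rate at α = 75 px.

## Worked example

```python
import adpt
from adpt.experiments import (train_desk_model, evaluate_pck,
                              make_training_frames, predict_track)
from adpt.metrics import drift_fraction

model, config, state = train_desk_model(seed=0)   # ~2 min on one CPU
test_frames = make_training_frames(32, seed=90)
print(evaluate_pck(model, config, test_frames))

frames, _ = adpt.generate_video(adpt.SceneSpec(seed=321), 200)
track = predict_track(model, config, frames)
print(drift_fraction(track.keypoints[:, 0], alpha=16.0).max())
```

Trained on 128 synthetic 64×64 frames, this prints (seed 0):

```
0.99375
0.0
```

i.e. 99.4% of held-out keypoints land within 0.15 × the instance's
bounding-box scale of the truth, and across a 200-frame synthetic video no
keypoint ever jumps more than 16 px between frames — the anti-drift
property at desk scale. The scripts in `examples/` walk through each
capability (scene generation, target encoding/decoding, training, mix-up,
the identity pipeline, the metric suite) and print what the numbers mean.

## Command line

```bash
adpt synth --preset single --n 128 --seed 0 --out dataset/
adpt train --config config.yaml --dataset dataset/ --seed 0 [--no-transformer] [--no-lrss]
adpt predict --checkpoint model/checkpoint --images video_frames/ --out pred/
adpt evaluate --track pred/track.csv --config config.yaml --skeleton dataset/skeleton.yaml
adpt mixup --pool1 a/ --pool2 b/ --background bg.png --n 100 --seed 0 --out social/
adpt convert --table CollectedData.csv --images proj/ --skeleton sk.yaml --out native/
```

Labeled datasets are read from the native layout (`images/` +
`annotations.csv` + `skeleton.yaml`) or from DeepLabCut-style multi-index
CSV/HDF5 tables; predicted tracks are written back in the DeepLabCut-style
x/y/likelihood layout.

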