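# voxrecon

Multi-view 2D→3D voxel reconstruction for biological image analysis, built
around a recurrent fusion network, together with the full evaluation suite
(voxel IoU, F1, MAE/MSE/RMSE, Chamfer distance, Earth Mover's Distance), an
epipolar two-view pose/Euler-angle pipeline, and a synthetic multi-view
dataset generator that replicates the structure of dental multi-view corpora
(32 objects × 18 views with OBJ + binvox ground truth and a relative-pose
CSV), so everything is testable without any downloads.

The intended users are researchers reconstructing 3-D occupancy volumes of
small rigid objects — teeth are the motivating case — from a handful of
calibration-free RGB views taken around the object.

## The model

Given an ordered sequence of views `x_1 … x_T`, the network predicts a binary
occupancy grid in three stages:

1. **Encoder.** Each view runs through a convolutional backbone truncated
   before its classification head (a compact 4-block CNN for desk-scale work,
   or a mobile-inverted-bottleneck backbone mirroring EfficientNet-B0's stage
   widths/strides). The flattened feature map feeds a fully connected layer
   sized lazily on the first forward pass, mapping to a fixed 1024-d latent,
   followed by LeakyReLU with slope 0.1.

2. **Recurrence: a 3-D convolutional LSTM grid.** An N×N×N grid of LSTM
   units with hidden size N_h fuses the view latents:

   ```
   f_t = σ(W_f x_t + U_f * h_{t-1} + b_f)
   i_t = σ(W_i x_t + U_i * h_{t-1} + b_i)
   s_t = f_t ⊙ s_{t-1} + i_t ⊙ tanh(W_s x_t + U_s * h_{t-1} + b_s)
   h_t = tanh(s_t)
   ```

   where `W_*` are linear maps from the latent onto the grid (one N_h-vector
   per unit), `*` is a same-size zero-padded 3-D convolution over the hidden
   grid, and there is deliberately **no output gate** — `h` is `tanh` of the
   cell state directly.

3. **Decoder.** The final hidden grid `h_T` is upsampled to resolution `N_v`
   by nearest-neighbour unpooling interleaved with 3-D convolutions
   (a 5-convolution *basic* variant and a *residual* variant with four skip
   connections), ending in a voxel-wise 2-class softmax. A voxel is occupied
   iff its probability exceeds a threshold `t` (strictly; default 0.5).

Training minimizes the mean voxel-wise cross-entropy between the occupied
probability and the binary ground truth. Everything — including the
gradients — runs on a small in-repo reverse-mode autodiff engine over numpy
(`voxrecon.autodiff`), so the package has no deep-learning framework
dependency and is fully deterministic for a fixed seed.

Evaluation follows the standard definitions: voxel
`IoU = |pred ∧ truth| / |pred ∨ truth|` after thresholding, Dice-form F1,
elementwise MAE/MSE/RMSE, Chamfer distance
`CD = Σ_p min_q ‖p−q‖² + Σ_q min_p ‖p−q‖²` on occupied-voxel-center clouds,
and exact assignment-based EMD `min_φ Σ ‖p − φ(p)‖`.

The pose module recovers relative camera motion between two views:
keypoints/descriptors (SIFT, ORB, corner+BRIEF) → cross-checked matching →
normalized 8-point fundamental matrix inside seeded, locally-optimized
RANSAC → essential matrix `E = KᵀFK` → cheirality-tested (R, t) → intrinsic
Z-Y-X Euler angles → DLT triangulation.

## Worked example

```python
from voxrecon import (build_dataset, load_multiview_dataset,
                      ReconstructionModel, TrainConfig, train, reconstruct,
                      EncoderConfig, LSTMConfig, DecoderConfig, evaluate_grids)

root = build_dataset(n_objects=3, n_views=5, n_v=16, out_dir="data",
                     seed=7, width=64, height=64)
samples = list(load_multiview_dataset(root))

model = ReconstructionModel(
    EncoderConfig(backbone="compact", latent_dim=1024, seed=0),
    LSTMConfig(grid_n=2, hidden=16, kernel=3, latent_dim=1024, seed=1),
    DecoderConfig(channels=(16, 32, 16, 8, 8), grid_n=2, resolution=16, seed=2),
)
history = train(samples, model, TrainConfig(epochs=60, seed=0))
print(f"loss {history.loss[0]:.4f} -> {history.loss[-1]:.4f}, "
      f"training IoU {history.iou[-1]:.4f}")

import numpy as np
grid, prob = reconstruct(np.stack(samples[0].views), model, threshold=0.5)
```

This prints

```
loss 0.6369 -> 0.0153, training IoU 0.9956
```

i.e. the jointly trained encoder/LSTM/decoder memorizes the three-shape
micro-dataset: the cross-entropy falls from near ln 2 (uninformed) to ~0.015
and the thresholded reconstruction overlaps the ground truth voxel grids at
IoU ≈ 0.996. The run takes about half a minute on one CPU core.

The same pipeline is available from the shell:

```bash
voxrecon generate-data --preset teethnet --resolution 32 --seed 3 --out teeth/
voxrecon train --data teeth/ --seed 0 --epochs 60 --out ckpt.npz
voxrecon reconstruct --ckpt ckpt.npz --views teeth/11/views --out pred.binvox
voxrecon evaluate --pred pred.binvox --truth teeth/11/model.binvox
voxrecon pose --img-a a.png --img-b b.png --detector sift --intrinsics K.json
```

For two rendered views of a checker-textured box 10° apart, `voxrecon pose`
reports (true angles `0.0744, 0.1580, 0.0059` rad):

```
"euler_zyx_rad": [0.0778, 0.1620, 0.0116],
"n_matches": 216,
"n_inliers": 171
```

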