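# Methods

This note documents the models, numerical choices and deliberate
interpretation decisions behind `voxrecon`, and what the synthetic-data tests
do and do not establish about real imagery.

## Reconstruction network

**Encoder.** A view (H×W×3 RGB in [0,1]) is mapped to a latent vector by a
truncated convolutional backbone, a flatten, a lazily-sized fully connected
layer and LeakyReLU(0.1). Two backbones share this contract:

* `compact`: four stride-2 conv blocks, channels 16→32→64→128, kernel 3.
  With 128×128 input the feature map is 8×8×128. This is the default for
  tests and desk-scale experiments.
* `b0_style`: stem conv (stride 2, 32 channels) followed by the
  mobile-inverted-bottleneck stage schedule of EfficientNet-B0 — expansion
  ratios (1,6,6,6,6,6,6), widths (16,24,40,80,112,192,320), repeats
  (1,2,2,3,3,4,1), strides (1,2,2,2,1,2,1), kernels (3,3,5,3,5,5,3) — without
  squeeze-excitation or batch normalization. The final 1280-channel head conv
  is excluded: features are taken at the penultimate stage (320 channels).

Weights are He-uniform initialized from the config seed. Externally trained
weights can be loaded by name/shape through `Encoder.load_backbone_weights`;
nothing in the repository requires a download. The backbone trains jointly
with the rest of the network. The fully connected layer's input size is fixed
on the first forward pass and serialized with the checkpoint; feeding a
different image size afterwards raises rather than silently re-initializing.

**3-D convolutional LSTM.** An N×N×N grid of LSTM units with hidden size
N_h and shared gate parameters:

    f = σ(W_f x + U_f * h + b_f)
    i = σ(W_i x + U_i * h + b_i)
    s' = f ⊙ s + i ⊙ tanh(W_s x + U_s * h + b_s)
    h' = tanh(s')

Interpretation decisions, in decreasing order of consequence:

1. **The latent transform T(x) is the identity**; each gate's `W` is the only
   learned input map (latent_dim → N³·N_h, reshaped onto the grid). This is
   the single most consequential reading of the recurrence, since nothing
   separates T from W functionally.
2. **No output gate**: `h = tanh(s)` exactly. This differs from a standard
   LSTM and is implemented literally. It bounds every hidden value in (−1,1)
   and gives the telescoping bound ‖s_T‖∞ ≤ T from a zero initial state
   (f, i ∈ (0,1), |tanh| ≤ 1), both of which are tested.
3. `U_*` are same-size zero-padded 3-D convolutions over the hidden grid.
   Neighborhood size is configurable; the default k=3 gives each unit its
   26-neighborhood, k=1 gives fully independent units.
4. Initial state is zeros; defaults N=4, N_h=128 follow the recurrent
   multi-view reconstruction lineage the architecture builds on. All three
   are config keys (`lstm.grid_n`, `lstm.hidden`, `lstm.kernel`).

Gate pre-activations are checked for finiteness at every step and the
offending gate is named in the error.

**Decoder.** The hidden grid (N_h channels at N³) is upsampled to N_v³ by
nearest-neighbour unpooling (factor 2) interleaved with zero-padded 3-D
convolutions (k=3) and LeakyReLU(0.1), ending in a 2-channel convolution and
a per-voxel softmax (max-shift stabilized) over (background, occupied).
The channel schedule lists five values — input plus four blocks — with the
final convolution making five in the basic variant. Unpooling is placed on
the first `log2(N_v/N)` blocks (three doublings for the default 4→32; the
diagrammatic sources do not pin the placement, so it is schedule-driven).
The residual variant adds identity skips around each of the four blocks,
with a 1×1×1 convolution on the skip when the channel count changes, then
the same final convolution. A transposed-convolution upsampler was
considered and rejected: replication is the simplest operator consistent
with "unpooling" and keeps the oracle tests exact.

**Training.** Loss is the mean voxel-wise binary cross-entropy on the
occupied-class probability, clipped to [1e−7, 1−1e−7] (the natural partner
of the 2-class softmax). Optimizer is Adam (lr 1e−3 default) with global
gradient-norm clipping at 10 — the un-gated `h = tanh(s)` recurrence
produces occasional large state gradients early in training. One step is
taken per sample per epoch in fixed order, so loss histories are exactly
reproducible for a given seed and thread count. Views per step default to
all available, with an optional fixed count or a random range per step.
Checkpoints are `.npz` archives of all float64 parameter tensors plus a JSON
config snapshot (including the resolved lazy-FC size); a save/load round
trip reconstructs bit-identically.

**Autodiff.** All of the above runs on `voxrecon.autodiff`, a ~400-line
reverse-mode engine over numpy float64: broadcast-aware elementwise ops,
matmul, shape ops, reductions, sigmoid/tanh/LeakyReLU, and dedicated
conv2d/depthwise-conv2d/conv3d/unpool3d primitives built on sliding-window
views so the inner loops are BLAS tensordots. Every primitive's gradient is
verified against central finite differences in the test suite, including one
end-to-end check through the full encoder→LSTM→decoder→loss graph.

## Voxel and mesh I/O

binvox v1 is read and written bit-exactly for canonical maximal-run
encodings; voxel order is the format's x-major, y-fastest convention
(flat index `x·N² + z·N + y`), runs capped at 255. Voxel (i,j,k) denotes the
cell centered at `translate + scale·((i,j,k)+0.5)/N`. OBJ handling covers
v/f records with fan triangulation of polygons and 1-based→0-based index
conversion; face topology and printed coordinates round-trip.

Mesh voxelization marks a cell occupied iff its center lies inside the mesh
by a +x ray-parity (crossing count) test. Ray origins are jittered by a
seeded ε (1e−7 of the grid side) in y and z to dodge edge- and
vertex-coincident intersections; triangles whose yz-projection is degenerate
are skipped (they cannot produce transversal crossings). Grid bounds are the
mesh AABB expanded by 2% and cubified to the largest extent. Non-watertight
meshes fall back to marking surface-crossed cells (dense seeded triangle
sampling), flagged via `meta['surface_only']`. At N_v=32 the unit sphere's
occupied fraction lands within 0.2% of the analytic volume ratio; the
acceptance check requires 10%.

## Synthetic data generator

The generator emulates the structure of multi-view reconstruction corpora:
per-object folders of rendered views plus OBJ/binvox ground truth and a CSV
(`image_name,rx,ry,rz,tx,ty,tz`) of poses relative to the first view
(intrinsic Z-Y-X angles in radians; the first row is exactly zero). The
`teethnet` preset fixes 32 tooth-like objects named by FDI/ISO tooth numbers
11–48 with 18 views each, replicating the published dental collection's
layout; `small` is a 4-object/5-view smoke-test preset.

Shapes are implicit solids (sphere, box, superellipsoid
`|x/a|^m + |y/b|^m + |z/c|^m ≤ 1`, and a tooth: a superellipsoid crown
blended by implicit union with 1–3 downward root lobes) surfaced by marching
cubes on a 32–48³ sample grid, then orientation-fixed outward. Meshes are
closed and deterministic per spec; all randomness derives from per-object
seeds spawned from the dataset seed, so datasets are reproducible
file-for-file.

Cameras are pinhole (`x_cam = R x_world + t`, looking along +z), equally
spaced in azimuth on a ring of configurable radius and elevation, all aimed
at the origin. Default intrinsics: fx = fy = 1.2·W, principal point at the
image center, W = H = 128 — generator-side ground truth only, since the
reconstruction network uses no explicit calibration. Rendering is a
z-buffered rasterizer with flat per-face Lambertian shading
(`ambient + (1−ambient)·max(0, n̂·l̂)`, constant background 0.05, optional
per-face albedo); under near-uniform reflection some views intentionally
look "2D-like", as flat multi-view renders of smooth objects do.

What the generator does **not** emulate: perspective texture detail,
specularities, shadows, sensor noise, soft-tissue context, or anatomically
accurate tooth morphology. Consequently, passing tests demonstrate that the
pipeline's mechanics (shapes, fusion, losses, metrics, formats, geometry)
are correct and trainable, not that the network generalizes to clinical
photographs or X-rays.

## Overfit experiment

The desk-scale training check uses 3 shapes × 5 views at 64×64, the compact
backbone, N=2, N_h=16, N_v=16, decoder schedule (16,32,16,8,8), Adam lr 1e−3,
60 epochs, fixed seeds throughout. It reaches training IoU ≈ 0.94–0.997
(seed-dependent) with the loss falling from ≈0.6 to below 0.1; the
acceptance bar is mean training IoU ≥ 0.85 with a decreased loss. This is a
memorization experiment — a stand-in demonstrating that the joint
architecture can be trained end-to-end — not a generalization claim.

## Two-view pose pipeline

Pixel coordinates: origin at the top-left pixel center, x right, y down.
Euler convention: intrinsic Z-Y-X (yaw β∈[−π/2,π/2]); at gimbal lock the
roll is set to 0, yaw absorbs the free angle and the result is flagged. The
convention cannot be disambiguated from error tables alone, so it is fixed
and stated rather than inferred.

Descriptor backends run behind one interface: SIFT (float descriptors, L2),
ORB and Harris-corner+BRIEF (binary, Hamming) via scikit-image. BRIEF
defines no detector, so it is paired with a Harris corner detector. The
`brisk` and `akaze` names are recognised but raise a "backend not available"
error — no installed library provides them. Matching is exhaustive
nearest-neighbour with symmetric cross-check, sorted by distance.

Fundamental-matrix estimation: Hartley-normalized 8-point inside seeded
RANSAC (Sampson distance, threshold 1 px, confidence 0.999, ≤10,000
iterations with a 500-sample floor), hypotheses ranked by MSAC-style
truncated cost. The top hypotheses are locally optimized — refit on their
consensus set to a fixed point — and the basin with the lowest truncated
cost wins. The local optimization matters: without it the recovered rotation
on the textured-box fixture varied by up to ~0.09 rad across RANSAC seeds
(different seeds landed in different consensus basins); with it the spread
collapses to <0.005 rad. Rank-2 is enforced by zeroing the smallest singular
value and F is normalized to unit Frobenius norm. Near-collinear inlier sets
are flagged degenerate.

`E = KᵀFK` is projected onto the essential manifold (singular values
(σ,σ,0), σ the mean of the top two). Pose recovery tests the four
decompositions by cheirality (strict majority of triangulated inliers at
positive depth in both views); since ‖t‖ is normalized to 1, a pure-rotation
scene shows up as triangulated depths many orders of magnitude above the
baseline, and a median depth above 1e6 raises a degeneracy error alongside
the failed-vote case. Triangulation is per-pair linear DLT from K[I|0] and
K[R|t], dropping behind-camera points.

On the textured-box fixture (subdivided cube with seeded random checker
albedos, 256×256 renders 10° apart): ground-truth correspondences recover
Euler angles to ~1e−15 rad and reproject to ~4e−13 px; SIFT-found
correspondences recover them to ~0.003 rad (bar: 0.05 rad). Angle errors in
the MAE/MSE/RMSE protocol are wrapped to (−π, π] before being scored.

## Problem sizes and runtime

The test suite and the acceptance script size every experiment for a single
CPU core: the overfit run is 60 epochs (~30 s), the dataset-structure
replication builds the full 32×18 preset at 128×128 with marching-cubes
grids of 32³ (~1.5 min), metric oracles use ≤50-point clouds (Chamfer) and
≤7-point clouds (exhaustive-permutation EMD), and the LSTM scalar-loop
oracle runs on N≤2, N_h≤2 grids. All tolerances in oracle comparisons are
1e−10 except where a quantity is only defined to test precision (hand
profiles at 1e−6).

## Known limitations

* The autodiff engine is float64 and single-threaded by design; it is not a
  performance substrate for ShapeNet-scale training, and resolutions above
  64³ are out of scope.
* The `b0_style` backbone mirrors stage widths/strides/kernels only; no
  squeeze-excitation, batch norm, or pretrained weights (a loading hook
  exists for externally trained tensors).
* EMD for unequal-size clouds subsamples the larger cloud (seeded, flagged)
  rather than solving the unbalanced transport problem; clouds above a few
  thousand points are outside the intended regime.
* The pose module handles exactly two views; no bundle adjustment or
  self-calibration.
* Reported percent-scale Chamfer/EMD normalizations vary across the
  literature; the evaluator exposes both raw and per-point-normalized values
  and makes no claim of comparability to any specific published scale.
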