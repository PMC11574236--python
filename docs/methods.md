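# Methods

## Problem and model

`toothseg` labels every face of a triangular dental-surface mesh with one
of 17 classes: gum (0) or one of 16 tooth positions in fixed
correspondence with FDI two-digit codes (classes 1–8 ↔ FDI 11–18,
9–16 ↔ 21–28; lower-arch codes 31–38/41–48 are accepted on input and map
to the same positional classes).

Each face is described by a 24-vector: the three vertex coordinates and
the face center (12 numbers), then the three vertex normals and the face
normal (12 numbers).  Features are z-scored per mesh, per dimension,
before entering the network.

The network has three parts:

1. **Local block.**  A stack of edge convolutions on a k-nearest-neighbor
   graph.  For face *i* with neighbors *j*, the default operator is

       x_i' = max_{j ∈ N(i)} h_θ(x_i ‖ x_j − x_i)

   with `h_θ` a shared single-layer MLP (linear → layer norm → leaky
   ReLU).  In `dynamic` mode the kNN graph is recomputed in the current
   feature space before each layer, so deeper layers connect faces that
   are semantically, not just metrically, close; `static` mode reuses
   the input-space graph.  Ablation axes kept in config: `local`
   (x_j − x_i only), `global` (x_i only), per-channel attention pooling
   (softmax-weighted sum scored by a second lightweight MLP h_σ), and a
   two-stream variant that processes coordinate and normal columns
   separately.  The attention operator pools h_θ(x_i ‖ x_j) while its
   scores see (x_i ‖ x_j − x_i); this asymmetry follows the printed
   construction, and a difference-form variant is available via
   `use_difference`.

2. **Dilated block.**  For each configured neighbor-set size k_b, the
   dilated edge convolution takes the k_b nearest faces of *i* by face
   center, farthest-point samples f of them (N_s(i)), and applies the
   combined edge convolution with max pooling over N_s(i).  Sampling
   from a progressively larger set (default k_b = 200, 600, 1800 at
   fixed f) widens the receptive field at constant edge count.  The
   sampled indices depend only on the face centers, so they are static:
   they can be precomputed per mesh and reused across epochs, and the
   precomputed and on-the-fly paths are bit-identical by construction.

3. **Head.**  Point-wise MLPs over the concatenation of every block
   output, optionally augmented with a globally max-pooled context
   vector, followed by a linear map to per-face logits and a softmax.

Training minimizes mean per-face cross-entropy with Adam (lr 1e-3,
halved every 30 epochs, 100 epochs, effective batch of 4 meshes —
meshes are never mixed within one graph; a batch accumulates per-mesh
gradients).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `target_faces` | 16000 | decimation target before feature extraction |
| `local_k` | 32 | kNN width of the local block (inferred default) |
| `n_local_layers` / `local_widths` | 3 / [64, 64, 128] | local stack depth and widths (inferred defaults) |
| `dilated_kb_list` | [200, 600, 1800] | enlarged neighbor sets of the stacked dilated layers |
| `dilated_f` | 32 | FPS sample size; chosen so a dilated layer costs about one local layer |
| `n_classes` | 17 | gum + 16 FDI tooth positions |
| `graph_mode` / `pooling` / `split_streams` | dynamic / max / off | the configuration that won the published ablation; other settings kept as ablation axes |
| `lr`, `lr_decay`, `lr_step_epochs`, `epochs` | 1e-3, 0.5, 30, 100 | published optimization schedule |
| `precision` | float64 | float32 available for faster CPU training |

Layer widths, normalization, activation and the exact skip topology are
not fixed by the method and live entirely in `NetworkConfig`.

## Numerical and design choices

* **Hand-written autodiff.**  The network runs on a small reverse-mode
  engine (`_autodiff.py`) over NumPy in double (or single) precision.
  Analytic gradients of every operator are property-tested against
  central finite differences (tolerance 1e-4 on small seeded
  instances).  Guided backpropagation is the same backward sweep with
  negative upstream gradients suppressed at every rectification;
  per-face salience is the norm of the input-row gradient.
* **Layer normalization, not batch normalization.**  Normalizing over
  the channel axis of each face keeps every face's output a function of
  its own receptive field; batch statistics would couple all faces of a
  mesh and destroy the locality that the receptive-field tests verify.
* **Determinism.**  All randomness (initialization, data order, dropout,
  mesh jitter) flows through explicit seeds.  kNN distance ties break by
  ascending index; FPS seeds at the candidate nearest the query and
  breaks ties by lowest index; argmax label ties take the lowest class.
  kNN candidates are preselected with the inner-product expansion and
  re-ranked with exactly computed squared differences, so results match
  the brute-force oracle including ties.
* **Exact simplification.**  Quadric edge collapse (area-weighted plane
  quadrics, optimal collapse position with midpoint fallback, link-
  condition check) is driven to the exact face target; an interior
  collapse removes two faces and a boundary collapse one, so odd
  remainders are absorbed by a final boundary collapse.  Labels transfer
  to the decimated mesh by nearest input-face centroid (lowest index on
  ties) — deterministic and oracle-checkable.
* **Per-mesh z-scoring** (population std) makes inference
  self-contained; constant columns are zeroed and the recorded moments
  invert the transform exactly.
* **Per-class accuracy is recall** (TP/(TP+FN)); classes absent from
  both truth and prediction are excluded from mIoU/Dice means (a flag
  switches to counting them as zero).  The aggregated table pools
  left/right confusion counts of the same tooth type before computing
  ratios.
* **Estimator shape.**  The primary user surface is
  `DilatedEdgeConvSegmenter`, a scikit-learn-style estimator
  (`get_params`/`set_params`/`clone`, `fit`/`predict`/`predict_proba`,
  trailing-underscore fitted attributes) over the functional modules.

## Synthetic arches

`fixtures.generate_arch` builds a parabolic gum band with hemispherical
tooth bumps, one per non-missing class, equally spaced by arc length;
the grid is decimated to the exact requested face count and vertex
positions carry seeded Gaussian jitter (default 0.05 mm).  Bumps come in
two shape families — narrow “incisor-like” (quadrant positions 1–4) and
wide “molar-like” (5–8) — so, within a family, a bump's class is
recoverable only from its position along the arch.  That reproduces, at
desk scale, the confusion mode the dilated receptive field addresses:
adjacent same-family teeth are locally indistinguishable.

What the generator does **not** emulate: real crown anatomy, scanner
noise and holes, sockets, misalignment/crowding, and the full 16,000-face
regime of clinical scans.  Passing the toy task therefore demonstrates
that the pipeline learns position-from-context on clean geometry; it
does not certify clinical accuracy.

## Problem sizes used in the tests

The toy learning task uses eight training arches and two held-out arches
of 2,000 faces each, a reduced network (two local layers, k = 16;
dilated k_b = 100 and 300 with f = 16; widths 24/48), one mesh per
optimizer step, 300 steps, five seeds, in single precision.  These sizes
were chosen so the whole suite runs comfortably on one CPU core; the
held-out face accuracy criterion is ≥ 0.95 for at least four of five
seeds.  Dilation geometry is measured on a 4,000-face arch with
k_b ∈ {200, 600, 1800}; the decimation contract is exercised at the full
16,000-face target.  Oracle-equivalence sweeps use ≥ 100 random
instances with M ≤ 500 and k ≤ 16.

## Known limitations

* CPU-only; a 16,000-face forward pass at full widths takes minutes, so
  full-scale training is impractical here — the architecture is the
  contribution, validated at reduced scale.
* No graph-cut or other post-processing of predictions, by design.
* No mesh repair: degenerate faces are rejected at read time, not fixed.
* The quadric collapser assumes a mostly-manifold input; heavily
  non-manifold meshes may fail with a simplification error rather than
  being repaired.
* Guided backpropagation is qualitative; salience maps are normalized
  per mesh for visualization and have no calibrated scale.
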