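# toothseg

Semantic segmentation of 3D dental surface meshes with dynamic and
dilated edge convolution.

Intraoral scanners produce triangular surface meshes of a patient's
dentition; orthodontic treatment planning needs every face of that mesh
labeled as gum or as one of the 16 teeth of the arch (FDI notation).
The hard cases are teeth that are locally indistinguishable — adjacent
molars or premolars share their geometry, and missing teeth shift the
whole arrangement — so a per-face classifier must see far beyond each
face's immediate neighborhood.  `toothseg` implements a graph neural
network built around a **dilated edge convolution** operator that widens
the receptive field at constant cost, plus everything needed to run it:
mesh I/O, quadric decimation with label transfer, per-face features, a
synthetic-arch generator, training, metrics, saliency, and a CLI.

## The model

Each of the M faces is a 24-vector (three vertex coordinates + face
center, three vertex normals + face normal), z-scored per mesh.  The
network outputs an M×17 row-stochastic matrix of class probabilities.

* **Local block** — stacked edge convolutions on a kNN graph rebuilt in
  the learned feature space before each layer:
  `x_i' = max_{j∈N(i)} h_θ(x_i ‖ x_j − x_i)`, with `h_θ` a shared MLP.
* **Dilated block** — for each enlarged neighbor-set size
  k_b ∈ {200, 600, 1800}: take the k_b nearest faces by face center,
  farthest-point sample f of them (N_s(i)), and apply
  `x_i^d = max_{j∈N_s(i)} h_θ(x_i ‖ x_j − x_i)`.  Sampling from a larger
  set at fixed f pushes samples outward, widening the receptive field
  without adding edges.  N_s depends only on the mesh geometry, so it is
  precomputed once per mesh and reused.
* **Head** — point-wise MLPs over all block outputs plus a global
  max-pooled context vector, then softmax.

Training: per-face cross-entropy, Adam, lr 1e-3 halved every 30 epochs.
Metrics: overall accuracy, per-class recall, mIoU (Jaccard) and Dice,
with left/right tooth types pooled in the aggregated table.  Guided
backpropagation produces per-face class-salience maps.

The network runs on a small NumPy reverse-mode autodiff core written for
this package (float64, optional float32), so it trains and runs on a
plain CPU with no deep-learning framework.

## Worked example

Train on synthetic arches (three-class toy task: gum / incisor-like /
molar-like bumps) with the scikit-learn-style estimator:

```python
from toothseg import ArchSpec, DilatedEdgeConvSegmenter, generate_arch
from toothseg.fixtures import family_labels

train_meshes = [generate_arch(ArchSpec(n_teeth=14, target_faces=2000, seed=s))
                for s in range(4)]
test_mesh = generate_arch(ArchSpec(n_teeth=14, target_faces=2000, seed=99))

seg = DilatedEdgeConvSegmenter(
    local_widths=(24, 24), local_k=16, dilated_kb_list=(100, 300),
    dilated_f=16, dilated_width=48, head_widths=(48, 24), n_classes=3,
    precision="float32", batch_size=1, epochs=50, max_steps=150,
    random_state=0)
seg.fit(train_meshes, [family_labels(m.face_labels) for m in train_meshes])

acc = seg.score([test_mesh], [family_labels(test_mesh.face_labels)])
print(f"held-out face accuracy: {acc:.3f}")
print(f"final training loss:    {seg.log_[-1]['loss']:.4f}")
sal = seg.salience(test_mesh, target_class=2)
tooth = family_labels(test_mesh.face_labels) == 2
print(f"mean salience on molar-like faces: {sal[tooth].mean():.3f}")
print(f"mean salience elsewhere:           {sal[~tooth].mean():.3f}")
```

Output:

```
held-out face accuracy: 0.976
final training loss:    0.0633
mean salience on molar-like faces: 1.701
mean salience elsewhere:           1.542
```

After 150 optimizer steps the model labels 97.6% of the held-out faces
correctly; the salience means show the molar-class score drawing on the
molar bumps themselves (and, through the dilated layers, on surrounding
context).  The full-size dental configuration is the constructor
default (`DilatedEdgeConvSegmenter()`): 17 classes, k_b = 200/600/1800,
16,000-face meshes.

The same pipeline is scriptable from the shell:

```bash
toothseg fixtures --n-teeth 14 --faces 4000 --seed 7 --out arch.ply --labels arch.json
toothseg preprocess arch.ply --out work/        # simplify + features + indices
toothseg train work/arch.preprocessed.npz --out model.npz
toothseg segment arch.ply --checkpoint model.npz --out pred.json --ply-out pred.ply
toothseg evaluate pred.json arch.json --out metrics.csv
toothseg saliency arch.ply --checkpoint model.npz --target-class 4 --out sal.ply
```

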