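# wbcnet

Classification of single white-blood-cell microscopy images into the four
leukocyte classes — **eosinophil, lymphocyte, monocyte, neutrophil** — with a
dilated-residual attention network, plus everything needed to exercise the
model end to end without external data: a seeded synthetic blood-smear
generator, the augmentation and training recipe, confusion-matrix metrics,
a block-ablation harness and Grad-CAM explanations.

Automated leukocyte differentials matter clinically because shifts in these
populations (and the appearance of abnormal lymphoblasts) are front-line
signals of acute lymphoblastic leukemia and other hematologic disease. The
four classes are visually separable by morphology: neutrophils have
multilobed nuclei, monocytes kidney-shaped nuclei, eosinophils granular
cytoplasm, lymphocytes a high nucleus-to-cytoplasm ratio.

## The architecture

For an input image $I_N$ (224×224×3 by default) the network computes

$$O_{CN} = f_{CN}(I_N), \quad O_{RDB} = f_{RDB}(O_{CN}), \quad
O_{GLFEB} = f_{GLFEB}(I_N, O_{RDB}), \quad O_{CSAB} = f_{CSAB}(O_{GLFEB})$$

* **Convolution stem** $f_{CN}$: 3×3 conv (32 filters) → 2×2 max-pool →
  group normalization (32 groups) → ReLU. Group norm uses the per-group
  statistics $\mu_i = \frac1m\sum_{k\in S_i} x_k$,
  $\sigma_i^2 = \frac1m\sum_{k\in S_i}(x_k-\mu_i)^2$,
  $\hat x_i = (x_i-\mu_i)/\sqrt{\sigma_i^2+\epsilon}$.
* **Dilated residual block (DRDB)** $f_{RDB}$: six residual branches —
  three plain, three dilated with the dilation sequence 1, 2, 4 (a 3×3
  kernel at dilation $d$ spans $3 + 2(d-1)$ pixels) — concatenated
  (6 × branch width channels) and reduced by a 1×1 convolution.
* **Global/local feature enhancement (GLFEB)**: a three-stage
  conv+GN+ReLU local path (64 → 128 → 64 filters) over $O_{RDB}$,
  concatenated with a projection of the stem's global feature and squashed
  by $\tanh$, doubling the channel count.
* **Channel & spatial attention (CSAB)**: channel gate
  $Q_c = \sigma(\mathrm{FC}(\mathrm{ReLU}(W_1 \cdot \mathrm{GAP}(A_t))))$
  and spatial gate $Q_s = \mathrm{ReLU}(W_2 * A_t)$ normalized to unit sum,
  applied as $A_t[c,i,j] \cdot Q_c[c] \cdot Q_s[i,j]$.
* **Fusion + head**: the attention output is summed elementwise with a 1×1
  projection of the GLFEB conv feature, then batch norm → 20% dropout →
  3×3 conv → global average pool → linear → softmax.

Training follows the published recipe: Adam, constant learning rate 0.01,
30 epochs (configurable), categorical cross-entropy. The default model has
~0.77 M trainable parameters versus ~11.2 M for an 18-layer residual
reference at the same input/output sizes.

## Worked example

```python
from wbcnet import CellImageClassifier, split_train_test
from wbcnet.synth import SyntheticCellSpec, generate_synthetic_cells

ds = generate_synthetic_cells(SyntheticCellSpec(canvas=56, seed=11), 100)
ds = split_train_test(ds, train_frac=0.8, seed=11)
train, test = ds.subset("train"), ds.subset("test")

clf = CellImageClassifier(stem_channels=8, drdb_branch_width=8,
                          glfeb_widths=(8, 16, 8), gn_groups=4,
                          head_channels=8, attention_fc_reduction=4,
                          epochs=15, seed=11)
clf.fit(train.images, train.labels)
print("test accuracy:", clf.score(test.images, test.labels))
```

```
test accuracy: 0.9375
```

That is: a width-reduced model trained for 15 epochs on 320 synthetic
56-pixel cell images classifies 75 of the 80 held-out images correctly —
the four morphologies are learned from the generator's nucleus shape,
granularity and nucleus-to-cell-ratio cues. With
`wbcnet.explain.grad_cam(clf.net_, image)` the resulting heatmap peaks
inside the cell body for the overwhelming majority of correctly classified
images.

The same pipeline is available from the shell:

```bash
wbcnet --seed 3 synth --out tree --n-per-class 25 --canvas 56
wbcnet --seed 3 train --data tree --out model.npz --canvas 56 --epochs 15
wbcnet --seed 3 evaluate --checkpoint model.npz --data tree --out metrics.json
wbcnet gradcam --checkpoint model.npz --image tree/monocyte/monocyte_00002.png --out cam.png
wbcnet --seed 3 ablate --data tree --out ablation.csv --epochs 2
```

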