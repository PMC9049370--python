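# histopatch

Two-stage nuclei segmentation and carcinoma recognition for H&E
histopathology images.

Pathology labs stain tissue with hematoxylin (nuclei, blue-purple) and
eosin (stroma, pink). Computer-aided recognition of carcinoma in such
slides hinges on segmenting the nuclei well: their density, size
distribution and crowding carry the diagnostic signal. `histopatch`
implements a pipeline for this, aimed at image-analysis researchers and
practitioners who want a classical, trainable-on-small-data alternative
to deep networks:

1. **Stain separation.** The optical density `V = ln(I0/I)` is factored
   as `V ≈ WH` by sparse non-negative matrix factorization,

   `min ½‖V − WH‖²_F + λ Σ_j ‖H(j,:)‖₁, W,H ≥ 0, ‖W(:,j)‖₂ = 1 (λ = 0.2)`,

   giving a hematoxylin-only "foreground" image and an eosin-only
   "background" image.
2. **Nuclei segmentation.** Frequency-tuned saliency gates nucleus seed
   markers on the foreground image; a marker-based watershed of the
   Sobel gradient then yields one labeled basin per nucleus.
3. **Features.** A 118-dim completed local binary pattern (CLBP, P = 8,
   R = 1, uniform-pattern sign + magnitude histograms) on the
   nuclei-segmented image is cascaded with a 128-dim color
   auto-correlogram (64 colors, chessboard distances {1, 3}) on the
   foreground image.
4. **Classification.** An RBF SVM (c = 2, g = 1) labels 20 random
   512×512 patches per image; the image is non-carcinoma iff strictly
   more than 10 patches vote non-carcinoma.

A synthetic H&E generator (Beer–Lambert forward model with known stain
matrix, nucleus masks and class structure) makes every stage testable
without external datasets.

## Worked example

```python
import numpy as np
from histopatch import (
    SceneSpec, make_scene, render_rgb, StainSeparator,
    segment_nuclei, dice,
)

spec = SceneSpec(height=128, width=128, n_nuclei=6,
                 radius_range=(6, 12), overlap_fraction=0.0,
                 noise_sd=0.0, seed=1)
gt = make_scene(spec)
img = render_rgb(gt)

sep = StainSeparator().fit(img)
print(np.round(sep.stain_matrix_, 3))
labels, nuclei_img = segment_nuclei(img)
print(int(labels.max()), round(dice(labels > 0, gt.mask), 3))
```

prints

```
[[0.619 0.112]
 [0.734 0.986]
 [0.281 0.126]]
6 0.986
```

The recovered stain matrix columns (hematoxylin, eosin) match the
generator's true vectors (0.65, 0.70, 0.29) and (0.07, 0.99, 0.11) to
cosine ≥ 0.99; the watershed finds all 6 nuclei and overlaps the true
mask with Dice 0.986.

The full recognition experiment on the synthetic two-class dataset
(20 train + 20 test images per class):

```python
from histopatch import run_synthetic_experiment
report = run_synthetic_experiment(n_per_class=20, seed=1)
print(report["image_wise"]["metrics"])
```

prints

```
{'accuracy': 97.5, 'sensitivity': 100.0, 'specificity': 95.0,
 'precision': 95.24, 'f1': 97.56}
```

i.e. 39 of 40 test images correctly recognized, with image-wise
ROC AUC 1.0.

There is also a CLI (`histopatch synth|separate|segment|features|
train|predict|evaluate|run-all`); see `histopatch --help`.

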