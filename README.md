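# raybok

Radiograph enhancement and automatic annotation with IRMA multi-axial codes:
a classic content-based image classification pipeline built from
contrast-limited adaptive histogram equalization (CLAHE), non-local means
denoising, repetition padding, pseudo-RGB layering, a dense-SIFT
Bag-of-Keypoints representation, and per-scheme Random Forests.

## Who this is for

Researchers working on content-based medical image retrieval and automatic
radiograph annotation who need a tested, reproducible implementation of the
standard enhancement + bag-of-visual-words + ensemble-classifier chain —
including a synthetic radiograph generator so every stage can be exercised
and benchmarked end to end without access to a clinical dataset.

## The problem and the method

A radiograph is annotated with a 13-character IRMA code `TTTT-DDD-AAA-BBB`
covering four independent axes: **T**echnical (modality), **D**irectional
(orientation), **A**natomical (body region) and **B**iological (organ
system).  Classification is evaluated under five schemes: each axis on its
own and the full joined code.

The pipeline prepares each grayscale image `I ∈ [0,1]^{H×W}` in one of six
input modes and classifies the result:

1. **CLAHE** — the image is split into an 8×8 tile grid; each tile's 256-bin
   histogram is clipped at `⌈0.01 · n_tile⌉` counts (excess redistributed
   uniformly), its cumulative distribution scaled to [0,1] forms the tile's
   intensity mapping, and each pixel bilinearly interpolates the mappings of
   its four surrounding tile centers.
2. **Non-local means** — each pixel becomes the weighted mean of its 9×9
   search window, `w(i,j) = exp(−‖P(i)−P(j)‖²_G / h²)` with `h = 0.05` and
   `‖·‖²_G` the Gaussian-weighted mean squared difference between 9×9
   patches.
3. **Repetition padding** — rescale so the long side is 512 px, then tile
   the image cyclically along the short axis to a 512×512 square.
4. **Layering** — stack original / CLAHE / NL-means as R/G/B channels,
   giving color-style input to feature extractors and networks.
5. **Bag-of-Keypoints** — dense SIFT (128-dim, 4-px grid, several cell
   sizes) → k-means codebook (`k = 1000`, 20 iterations, random-point
   init) → nearest-word quantization → 2×2 spatial histograms (4·k dims) →
   PCA to 100 dims, fit on training data only.
6. **Random Forest** — 1,000 bagged trees grown to purity, one forest per
   classification scheme; accuracy is the exact-match fraction.

## Worked example

```python
import numpy as np
from raybok import (
    GeneratorConfig, generate_dataset, run_experiment, RfConfig,
)

cfg = GeneratorConfig(n_images=300, seed=11)       # 48 synthetic IRMA codes
path, table = generate_dataset(cfg, "dataset")
report = run_experiment(
    table.subset("train"), path, table.subset("test"), path,
    modes=["original", "padded", "layered", "padded_layered"],
    schemes=["T", "D", "A", "B", "IRMA"],
    rf_config=RfConfig(n_trees=100),
    extractor_params={"k": 50, "pca_dim": 100},
    seed=11,
)
print(report.to_frame())
```

prints the accuracy matrix over input modes × schemes (one run on the
synthetic benchmark):

```
                         T         D         A         B      IRMA
Image Padding          1.0  0.791667  0.770833  0.854167  0.770833
Image Padding/Layered  1.0  0.833333  0.750000  0.916667  0.750000
Image Layered          1.0  0.937500  0.979167  0.958333  0.958333
Original Image         1.0  0.958333  0.979167  0.937500  0.937500
```

Each cell is the exact-match test accuracy of the per-scheme Random Forest
on that input mode.  The T scheme (2 synthetic technique classes) is
easiest; the A scheme and the full 48-class IRMA code are hardest, and the
padded modes trade some texture-frequency information (rescaling changes
pixel periods) for a uniform geometry.

The same experiment is available from the shell:

```bash
raybok synth --out-dir dataset --n-images 300 --seed 11
raybok run --labels dataset/labels.csv --image-dir dataset --out-dir results --seed 11
```

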