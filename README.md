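# leafclar

Citrus-leaf disease images photographed in orchards are routinely degraded —
low light under cloud, haze, uneven illumination — and several diseases
produce confusably similar lesions.  `leafclar` is a toolkit for that
problem with two parts:

1. **AMSR enhancement** — an adaptive multi-scale retinex algorithm.  Each
   colour channel is decomposed into illumination and reflectance
   (`log R = log S − log(G_σ ∗ S)`) at three Gaussian-surround scales, and
   the scales are blended per pixel by a frequency-comparison coefficient
   `A = a1·arccot(σ_local) + a2` that favours the small surround at edges
   and the large surround in flat regions.  Channels are merged with a
   percentile stretch and brightness-compensated chromaticity restoration
   `R_j = (I_j / I) · λ`, preserving hue while normalizing illumination.

2. **MF-RANet classification** — an ELU-activated ResNet50-style backbone
   with a residual attention module after every stage
   (`H = (1 + M)·T`, mask `M ∈ [0,1]`), a detail road that fuses the four
   stage maps through lateral projections, residual feature enhancement and
   adaptive spatial fusion, shared auxiliary heads for consistency
   supervision, and a label-smoothed softmax classifier
   (`P_i = 1−ε` on the true class, `ε/(K−1)` otherwise) over six classes
   (healthy + five diseases).  The network runs on a small NumPy autodiff
   engine bundled with the package — no deep-learning framework required.

A synthetic-fixture generator emulates the study conditions (six lesion
classes, sunny/cloudy/foggy/uneven acquisition, seeded noise degradations)
so the entire pipeline is testable without any image download.

## Worked example

```python
import numpy as np
from leafclar.synth import SyntheticSpec, generate_dataset
from leafclar.amsr import enhance, EnhancementConfig
from leafclar.image import RgbImage
from leafclar.data import SplitSpec, split_manifest
from leafclar.model import MFRANet, ModelConfig
from leafclar.traineval import TrainConfig, train, confusion, metrics

# 120 synthetic leaf images (20 per class) under mixed acquisition conditions
manifest = generate_dataset(SyntheticSpec(n_per_class=20, seed=1), "work/raw")

# enhance every image, then split 6:2:2 stratified by class
for p in manifest.records["path"]:
    enhance(RgbImage.load(f"work/raw/{p}")).save(f"work/amsr/{p}")
manifest = split_manifest(manifest, SplitSpec(ratios=(6, 2, 2), seed=2))

# train the width-0.25 reduced network
model = MFRANet(ModelConfig(width_multiplier=0.25, seed=3))
model, log = train(model, manifest,
                   TrainConfig(batch_size=16, epochs=12, seed=4), "work/amsr")

cm = confusion(model, manifest, "test", "work/amsr")
rep = metrics(cm)
print(f"test accuracy {rep.accuracy:.3f}  macro F1 {rep.macro_f1:.3f}")
```

The training log prints one line per epoch, e.g.

```
epoch   1  lr 0.001  loss 1.9910  train_acc 0.431
epoch   2  lr 0.001  loss 1.7058  train_acc 0.611
epoch   3  lr 0.001  loss 1.4965  train_acc 0.736
```

— the loss is the label-smoothed composite (main + 0.25 × auxiliary) and
`train_acc` the running accuracy over that epoch's batches.  On this
120-image desk-scale problem the reduced model reaches ≥ 95% training
accuracy within 30 epochs; `metrics` reports per-class precision/recall/F1
(`P = TP/(TP+FP)`, `R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`) and their unweighted
macro averages from the 6×6 confusion matrix.

A command-line interface mirrors the library:

```sh
leafclar synth --out data/ --n-per-class 20 --seed 1
leafclar enhance data/*.png --out enhanced/
leafclar data split --manifest data/manifest.csv --ratios 6,2,2 --seed 2 --out split.csv
leafclar train --manifest split.csv --root enhanced/ --out model.npz --width 0.25
leafclar eval --checkpoint model.npz --manifest split.csv --root enhanced/ --report report.json
leafclar robustness --checkpoint model.npz --manifest split.csv --root enhanced/ --noise gaussian:0.02,0.05,0.1
```

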