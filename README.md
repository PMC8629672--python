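# fwnnet

A fuzzy wavelet neural network (FWNNet) toolkit for grayscale-image
classification and supervised tumor segmentation, aimed at MRI-style
brain-tumor workflows: four-class diagnosis (Normal, Glioma, Meningioma,
Pituitary) from histogram features, and pixel-level tumor-mask prediction
from paired ground-truth masks.  Everything runs on synthetic MRI-like
phantoms generated by the package itself, so the full pipeline is testable
without any image download.

## The model

The FWNNet is a first-order TSK fuzzy system whose rule consequents are
wavelet networks.  With inputs x ∈ ℝⁿ and rules k = 1..M:

    μ_kj = exp(−((x_j − c_kj)/σ_kj)²)          Gaussian memberships
    O_k  = Π_j μ_kj                             firing strength (product AND)
    Ψ_ik = Π_j ψ((x_j − b_ijk)/a_ijk)           product wavelets, ψ = Mexican hat
    Y_k  = Σ_i w_ik Ψ_ik + ȳ_k                  rule consequent
    y    = Σ_k O_k Y_k / Σ_k O_k                defuzzified output

For classification, y is rounded (half away from zero) and clamped to the
label range.  Training is hybrid: a small particle swarm (20 particles, 50
generations, c1 = c2 = 2, linearly decreasing inertia; optionally blockwise
"inline" over the (c, σ), (b, a), (w, ȳ) groups) initializes
Θ = {c, σ, b, a, w, ȳ}, then exact-gradient descent with per-group
learning rates refines it.

Feature extraction models each image's 256-bin intensity histogram as a sum
of four Gaussians, A_g·exp(−((v − m_g)/s_g)²), and uses the four sorted
mode means as the feature vector.  Segmentation Gabor-transforms the image,
pairs each m×m mask patch with its co-centered 2m×2m input window, trains
an FWNNet regressor on (window, mask pixel) pairs, and reassembles
per-patch predictions into a tumor score map.  See `docs/methods.md` for
the full account.

## Worked example

```python
import numpy as np
import fwnnet as fw

# 2000 synthetic histogram-feature vectors, 500 per class
X, y = fw.generate_class_dataset(500, seed=1)

params, cfg, trace = fw.train_classifier(X, y, num_classes=4, seed=1)
pred = fw.predict_labels(X, params, cfg)
print(f"train accuracy: {np.mean(pred == y):.4f}")
print(f"final train RMSE: {trace.train_rmse[-1]:.4f}")

cm = fw.confusion(y, pred, 4)
print(f"class-0 sensitivity: {fw.sensitivity(cm, 0):.3f}")
```

prints

```
train accuracy: 1.0000
final train RMSE: 0.1481
class-0 sensitivity: 1.000
```

i.e. after hybrid training every one of the 2000 training samples rounds to
its own label (the continuous output still sits up to ~0.15 away from the
integer targets on average — rounding absorbs it).

Segmentation on phantoms:

```python
pairs = fw.generate_segmentation_set(20, seed=1, image_side=128)
train, test = pairs[:15], pairs[15:]
model = fw.fit_segmentation([p[0] for p in train], [p[1] for p in train],
                            scheme=fw.PatchScheme(m=4),
                            bank=fw.GaborBank(wavelength=4.0), seed=1)
smaps, masks = zip(*[(fw.segment_image(img, model)[0], msk)
                     for img, msk in test])
_, (fpr, tpr, auc) = fw.segmentation_roc(smaps, masks)
print(f"pooled test AUC: {auc:.3f}")   # -> pooled test AUC: 0.963
```

The same pipeline is scriptable from the shell:

```bash
fwnnet simulate classification --n-per-class 25 --seed 0 --out data/
fwnnet extract  --images data/ --out features.csv
fwnnet train    --features features.csv --labels data/labels.csv --out model.json
fwnnet evaluate --model model.json --features features.csv \
                --labels data/labels.csv --report report.json
fwnnet simulate segmentation --n 20 --side 128 --seed 0 --out seg/
fwnnet segment train --images seg/images --masks seg/masks --out seg.json
fwnnet segment apply --images seg/images --model seg.json --out pred/
```

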