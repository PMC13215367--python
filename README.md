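# metseg

Detecting and delineating **multiple brain metastases (BMs)** on
contrast-enhanced T1 MRI is hardest exactly where it matters clinically: for
small lesions (longest axis < 3 mm) that stereotactic-radiosurgery planning
must not miss.  `metseg` is a scale-configurable toolkit that implements the
training and evaluation machinery of a lesion-focused segmentation pipeline
— and, since clinical volumes cannot be redistributed, exercises everything
end-to-end on seeded synthetic lesion phantoms.

The package provides, as independently testable modules:

* **`metseg.phantom`** — synthetic "patients": T1c-like volumes containing
  randomly oriented ellipsoidal enhancing lesions whose longest-axis sizes
  follow the three-stratum mixture seen in multi-institutional BM cohorts
  (25.73% < 3 mm, 40.92% in [3, 6] mm, 33.35% > 6 mm), plus controlled
  prediction-perturbation fixtures.
* **`metseg.network`** — an encoder–ViT–decoder hybrid: CNN encoder down to
  an 8×8×8 bottleneck (L = 512 tokens), self-attention over the tokens, CNN
  decoder with skip connections and two-class softmax.  Built on a compact
  numpy reverse-mode autodiff core (`metseg.autodiff`).
* **`metseg.losses`** — the composite objective
  `L = L_Dice + (1−w)·L_CE + w·L_LRP` with the **LRP patch-focal term**: the
  volume is split into 8×8×8-voxel patches, each labelled positive iff it
  contains a lesion voxel, and a focal cross-entropy
  `−[y(1−q)^γ log q + (1−y)q^γ log(1−q)]` (γ = 0.5, default w = 0.4)
  concentrates gradient on hard lesion-bearing patches.
* **`metseg.clp`** — **contrastive latent pretraining**: the lesion mask is
  max-pooled onto the bottleneck grid and an InfoNCE-style loss pulls
  lesion tokens together while contrasting them against lesion-free tokens,
  plus a latent class-separation score and t-SNE export.
* **`metseg.trainer`** — the two-stage schedule: stage 1 trains encoder+ViT
  with the contrastive loss (decoder frozen), stage 2 fine-tunes the decoder
  with the composite loss (encoder+ViT frozen); SGD with Nesterov momentum
  0.99 and polynomial learning-rate decay from 0.001.
* **`metseg.lesion_eval`** — the lesion-wise protocol: 1 mm morphological
  closing of the prediction, 26-connected components, coverage matching
  (`CV = |A∩B|/|B|`, TP iff CV ≥ 0.5, one-to-one greedy), size-stratified
  sensitivity/precision, per-lesion Dice for GT ≥ 3 mm, lesion- and
  patient-level aggregation.

See `docs/methods.md` for the model details, default parameters and the
limitations of the phantom-based validation.

## Worked example

Simulate a small cohort, run both training stages and evaluate:

```bash
metseg simulate --n-patients 5 --shape 32 --n-lesions 4 --seed 5 --out cohort/
```

```
wrote 5 phantoms to cohort/
```

```python
import numpy as np
from metseg.clp import CLPConfig, pretrain, separation_score, subsample_mask
from metseg.network import NetConfig, build_network, extract_latent
from metseg.trainer import TrainConfig, finetune, load_cohort
from metseg.losses import LossConfig
import json

manifest = json.load(open("cohort/manifest.json"))
vols, masks = load_cohort(manifest, "cohort")
net = build_network(NetConfig(input_shape=(32, 32, 32), n_down=2,
                              base_channels=4, vit_layers=2, vit_dim=16,
                              vit_heads=4), seed=5)

sub = subsample_mask(masks[0])
print("separation before:", round(separation_score(
    extract_latent(net, vols[0]), sub), 2))
pretrain(net, manifest, CLPConfig(epochs=30),
         train_config=TrainConfig(epochs_pretrain=30, seed=5),
         cohort_dir="cohort")
print("separation after: ", round(separation_score(
    extract_latent(net, vols[0]), sub), 2))
```

```
separation before: 2.75
separation after:  7.99
```

The separation score is the distance between the BM and non-BM token
centroids in units of the within-class spread (after normalising by the
lesion-free statistics): contrastive pretraining roughly triples it, which
is the mechanism by which the pretrained encoder reduces false positives.

Fine-tuning the decoder then turns the latent contrast into a segmentation;
on a 20-phantom cohort rich in sub-3 mm lesions, 20 desk-scale epochs with
the patch-focal term enabled (`w = 0.4`) reach 0.90 small-lesion
sensitivity (102 TP / 10 FP over the cohort), while the plain Dice+CE
objective (`w = 0`) reaches only 0.30 at the same budget — the
class-imbalance failure mode the LRP term exists to fix.

Evaluate any prediction directory against ground truth:

```bash
metseg evaluate --gt gt_masks/ --pred pred_masks/ --report report.json
```

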