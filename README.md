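# pneumonet

Attention-enhanced residual classification of pneumonia in chest X-ray
images, exercised end-to-end on a built-in synthetic radiograph phantom
generator.

Pediatric pneumonia screening from frontal chest radiographs is a binary
image-classification problem with a strongly imbalanced class distribution
(pneumonia studies typically outnumber normals by roughly 2.7:1). This
package implements, in pure numpy with explicit gradients:

- **Side-branch attention blocks.** Each block passes the feature map
  `F ∈ ℝ^{H×W×C}` through a main 3×3 convolution and, in parallel, through
  two side branches that reduce it to `H/s × W/s × C/r` by strided
  convolution and restore `H×W×C` by transposed convolution. The fused map
  is `F + MainConv(F) + Σ_b Up_b(Reduce_b(F))` (additive mode; a sigmoid
  gate `σ(Σ_b …) ⊙ MainConv(F)` is available), so every block is
  shape-preserving and residual. A full classifier is stem convolution →
  `n` blocks → global average pooling → linear head with 2 logits.
- **Channel attention** (optional, off by default): gates
  `g = σ(W₂ ReLU(W₁ GAP(F)))` rescale the channels of `F`.
- **Scaled dot-product attention** `Attention(Q,K,V) = softmax(QKᵀ/√d_k)V`
  as a standalone primitive.
- **A class-count-normalized focal loss.** The focal loss
  `FL(p_t) = −α_t (1−p_t)^γ log p_t` is extended with per-branch factors
  `1/√n`: the `y=1` branch is scaled by `α/√n_a` and the `y=0` branch by
  `(1−α)/√n_b`, up-weighting the minority class during training. Both the
  verbatim count pairing and a per-class pairing are implemented (the
  `count_mapping` switch), since the two differ under the label convention
  1 = pneumonia.
- **A residual (ResNet-style) baseline** and the canonical ResNet-50 shape
  walk (224×224 input → 112×112×64 → 56×56×64 → … → 7×7×2048).
- **Evaluation metrics** — accuracy, precision, recall/sensitivity,
  specificity, F1 — computed with exact rational arithmetic from the
  confusion matrix (positive class = pneumonia).
- **A seeded AdamW training loop** (decoupled weight decay, step
  learning-rate schedule ×0.1 every 5 epochs) and a three-variant ablation
  runner: residual baseline + cross-entropy, + side-branch blocks,
  + side-branch blocks + modified focal loss.

Because no public radiograph collection ships with the package, the
`synthetic_xray` module generates chest-radiograph-like phantoms: a bright
thorax with two darker elliptical lung fields and rib bands, where positive
samples carry bright infiltrates, nodules, lobar consolidation, a lung
density lift and pleural bands — all strictly inside the lung masks, so the
task is learnable by construction and every claim in the test suite is
checked on data the package itself produces. See `docs/methods.md` for the
model and generator details and their limitations.

## Worked example

```python
import dataclasses
from pneumonet.metrics import ConfusionMatrix, report_from_cm
from pneumonet.synthetic_xray import DESK_SPEC, generate_dataset, split_dataset
from pneumonet.model_zoo import DESK_CONFIG, build_attention_net
from pneumonet.train_eval import DESK_TRAIN_CONFIG, train, evaluate

# metrics from a 416-image validation confusion matrix
print(report_from_cm(ConfusionMatrix(tp=207, fp=12, tn=196, fn=1)).to_json())

# train the attention net on the desk-scale synthetic preset
spec = dataclasses.replace(DESK_SPEC, seed=0)             # 270 pneumonia / 100 normal, 64x64
samples, manifest = generate_dataset(spec)
train_set, val_set = split_dataset(samples, (210, 80), (60, 20), seed=0)
model = build_attention_net(DESK_CONFIG, seed=0)
model, history = train(model, train_set, val_set,
                       dataclasses.replace(DESK_TRAIN_CONFIG, seed=0))
print(history.to_frame().to_string(index=False))
print(evaluate(model, val_set).to_json())
```

This prints the exact metric values implied by the confusion-matrix counts
(accuracy 403/416 = 0.96875, precision 207/219 ≈ 0.945205, recall
207/208 ≈ 0.995192, specificity 196/208 ≈ 0.942308, F1 ≈ 0.969555), then the
training trace

```
 epoch  train_loss  val_accuracy     lr
     0    0.362765          0.75 0.0030
     1    0.137434          0.75 0.0030
     2    0.069523          1.00 0.0030
     3    0.044598          1.00 0.0030
     4    0.031790          1.00 0.0030
     5    0.014668          1.00 0.0003
```

— the loss falls monotonically, validation accuracy reaches 1.0 by epoch 2
(the noise level is low and the phantom classes are separable by
construction), and the learning rate drops ×0.1 at epoch 5 per the step
schedule — and finally the validation report
`{"accuracy": 1.0, ..., "tp": 60, "fp": 0, "tn": 20, "fn": 0}`.

The same pipeline is available from the shell:

```bash
pneumonet simulate --preset desk --out data/ --seed 0
pneumonet train --preset desk --data data/ --out run/ --seed 0
pneumonet evaluate --model run/ --data data/
pneumonet ablate --preset desk --out ablation/ --seeds 5
```

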