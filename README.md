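# segresdeit

Multi-task deep learning for cervical cytology screening: one network that
simultaneously **segments** abnormal epithelial regions (a per-pixel
probability map) and **classifies** whole bright-field Pap-smear images as
normal vs. abnormal (a per-image probability). The package provides the full
pipeline — deterministic preprocessing, the hybrid network, the composite
loss, the training regimen, an evaluation suite, ablation variants, and a
synthetic cytology-image generator so everything is testable end to end on a
laptop CPU with no external data.

## The model

Three components share one backbone:

* **Indexed encoder–decoder (SegNet-style).** Blocks of 3×3 conv → batch
  norm → ReLU, each closed by 2×2 max pooling that records the argmax
  position of every window. The decoder mirrors the encoder and upsamples by
  *index-guided unpooling* — each value is placed back at its recorded
  position — which preserves lesion boundaries, then refines with
  convolutions and emits a sigmoid probability map.
* **Residual bottleneck bridge (ResNet-style).** Stride-1 bottleneck stages
  (1×1 reduce → 3×3 → 1×1 expand with identity shortcuts) deepen the shared
  representation between encoder and both heads.
* **Token transformer classifier (DeiT-style).** The bridge feature map is
  cut into non-overlapping patches, linearly embedded, prepended with
  learnable class and distillation tokens plus positional embeddings, and
  processed by pre-norm self-attention blocks; an MLP head on the tokens
  yields the image-level probability. Without a teacher, the distillation
  token is supervised by the ground-truth label and the two logits are
  averaged at inference.

Training minimises the multi-task objective

```
L_seg   = λ₁ · L_BCE + λ₂ · L_Dice        (soft Dice, smoothing ε)
L_total = L_seg + α · L_cls               (λ₁=0.6, λ₂=0.4, α=1.0)
```

with Adam (lr 1e-4, weight decay 1e-5), cosine-annealed learning rate,
micro-batch 8 with gradient accumulation over 2 steps (effective batch 16),
up to 30 epochs with early stopping on validation loss (patience 10), and
dropout 0.3 in the decoder and transformer head.

Evaluation uses confusion-count metrics: accuracy, precision, recall, F1,
Dice = 2TP/(2TP+FP+FN) (identical to F1 on binary counts), IoU =
TP/(TP+FP+FN), and ROC/AUC — at both pixel and image level.

## Worked example

Train a small model on generated cytology fixtures and evaluate it:

```python
import segresdeit as sd

train_set = sd.generate_dataset(sd.SynthConfig(
    n_images=40, image_size=(64, 64), lesion_probability=0.7, seed=11))
test_set = sd.generate_dataset(sd.SynthConfig(
    n_images=16, image_size=(64, 64), lesion_probability=0.7, seed=12))

cfg = sd.ModelConfig(input_size=(64, 64, 3),
                     encoder_blocks=((2, 8), (2, 16), (2, 32)),
                     bridge_stages=1, embed_dim=32, depth=2, heads=2,
                     dropout_rate=0.1, variant="segresdeit")
model = sd.build_model(cfg, seed=5)
sd.train(model, train_set, test_set,
         sd.TrainConfig(learning_rate=3e-3, max_epochs=80,
                        early_stop_patience=80, augment=False, seed=5))

print(sd.evaluate_model(model, test_set, mode="pixel").rounded())
```

Output from this exact run:

```
{'accuracy': 0.9961, 'precision': 0.9239, 'recall': 0.9719, 'f1': 0.9473,
 'dice': 0.9473, 'iou': 0.8999, 'auc': 0.9993}
```

i.e. on 16 held-out same-generator images the model recovers lesion masks
with pixel-level Dice ≈ 0.95 and IoU ≈ 0.90; `mode="image"` reports the
classification head the same way. Metrics can also be derived directly from
confusion counts:

```python
from segresdeit import ConfusionCounts, MetricReport
MetricReport.from_counts(ConfusionCounts(tp=903, tn=361, fp=41, fn=33)).rounded()
# {'accuracy': 0.9447, 'precision': 0.9566, 'recall': 0.9647,
#  'f1': 0.9606, 'dice': 0.9606, 'iou': 0.9243, 'auc': None}
```

A `segresdeit` console command wraps the library: `synth`, `train`,
`evaluate`, `predict`, `metrics-from-counts`, `ablation` (see `--help`).

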