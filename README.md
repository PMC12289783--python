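# ddunet — dual-decoder U-Net for class-imbalanced lesion segmentation

Lesions in medical images — thyroid nodules and breast masses in
ultrasound, tumours in liver CT — typically cover a few percent of the
pixels (imbalance of roughly 1:9 down to 1:50).  Networks trained with
plain pixelwise cross-entropy drift toward the background class and miss
exactly the pixels a clinician cares about.  `ddunet` is a CPU-scale,
pure-NumPy implementation of a segmentation architecture and loss family
built against that failure mode, for researchers who want an inspectable,
fully deterministic reference rather than a GPU framework.

The model is a U-Net with:

* an encoder with **two contraction paths** (the second re-consumes the
  first's features at every level) and a width-doubling bottleneck
  (1024 x 32 x 32 for a 256 x 256 input),
* **BiFPN** multi-scale fusion with fast-normalized learnable weights
  `U = Σ_p relu(w_p)/(ε + Σ_q relu(w_q)) · I_p` (ε = 1e-4),
  depthwise-separable convolutions and Swish,
* a **masked coarse-to-fine attention module**: candidate embeddings
  predict a coarse mask `sigmoid(T_o Q^T)`, then refine by cross-attention
  `T ← T + softmax((T M_q)(Q M_k)^T + f(a)) (Q M_v)` confined to the
  predicted foreground,
* **dual decoders** with pooling-integration skip fusion, emitting a
  foreground map `M_F` and a background map `M_B`, fused as
  `O = (σ(M_F) + 1 − σ(M_B)) / 2`,
* an **integrated loss** `I = α·D + β·C + δ·R + γ·B` combining foreground
  Dice, both-class Dice, per-class soft-recall and BCE terms, with the
  decoder losses combined at weights 0.6 / 0.2 (+ 0.2 on the fused output).

Everything runs on a small reverse-mode autodiff engine over NumPy
(`ddunet.nn`) — no deep-learning framework is required.  A bundled
synthetic generator produces imbalanced lesion datasets (controllable
foreground fraction, contrast, noise) emulating the 1:9 and 1:50 regimes,
so the whole pipeline is exercised end-to-end on a laptop CPU.
See `docs/methods.md` for the model details, assumptions and limitations.

## Worked example

```
$ ddunet simulate --out run1
wrote 100 pairs to run1/data (manifest run1/data/manifest.tsv)
realized foreground fraction: mean 0.0988 (range 0.0801..0.1196)

$ ddunet train --out run1
checkpoint: run1/checkpoint.npz
best val loss 0.1899 at epoch 39

$ ddunet eval --checkpoint run1/checkpoint.npz --data run1/data --out run1 --split test
aggregate (macro mean over images):
  precision: 0.8783
  recall: 0.9711
  iou: 0.8569
  dsc: 0.9220
report: run1/metrics.csv
```

This is the fully-defaulted desk-scale run: 100 synthetic 64 x 64 images in
the ~1:9 regime (the realized mean foreground fraction, 0.0988, is printed
so you can check the imbalance), a reduced-width model, 40 epochs of SGD
(lr 0.01, momentum 0.9, weight decay 1e-4, batch 16).  The evaluation is on
the held-out 10% test split; recall 0.97 means almost no lesion pixels are
missed, and DSC 0.92 summarizes overlap.  `ddunet predict --checkpoint ...
--image img.png --out mask.png` segments a single PNG.  All commands accept
`--config config.yaml` with nested `synthetic / augment / model / train /
loss` sections; the resolved config is echoed into the output directory.

As a library:

```python
from ddunet import (SyntheticConfig, generate_dataset, ModelConfig,
                    TrainConfig, train, evaluate)

data = generate_dataset(SyntheticConfig(n_images=60, image_size=64,
                                        fg_fraction_range=(0.04, 0.06)))
res = train(data, ModelConfig.tiny(64), TrainConfig(max_epochs=20, eval_every=5))
rows, agg = evaluate(res.model, res.splits["test"])
print(agg["recall"], agg["dsc"])
```

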