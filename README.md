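# pdfuse

Severity classification of Parkinson's-disease brain-slice images from
fused, attention-refined inputs — a tested, reusable implementation of a
four-part pipeline:

1. **Fusion preprocessing** — a contrast-enhanced copy
   R = W∘P + (1−W)·g(P, k), with the beta-gamma camera-response transform
   g(P, k) = e^{b(1−k^a)}·P^{k^a} and an entropy-optimal exposure ratio k,
   is blended with a mean-filtered copy; per-pixel blend weights come from
   the multi-scale morphological gradient
   M = Σ_t w_t (f ⊕ SE_t − f ⊖ SE_t), w_t = 1/(2t+1), used as a focus
   measure.
2. **PCFAN** — a three-scale encoder (32/64/128 channels) fused by a pyramid
   of exactly four squeeze-excitation-style channel-attention blocks
   (σ(φ₂(ReLU(φ₁(μ)))) gating) and reconstructed by a single convolution;
   pretrained by self-supervised MSE reconstruction.
3. **Classifier** — a compact MobileNetV3-style bneck stack (inverted
   residuals, squeeze-excitation, h-swish(x) = x·ReLU6(x+3)/6) for the three
   severity classes mild / moderate / severe.
4. **IDMO** — the improved dwarf-mongoose optimizer (alpha / scout /
   babysitter phases, step damper ω = e^{−4(C/Max)²}, exchange scale
   CF = (1−C/Max)^{2C/Max}) as a bound-constrained minimizer, used for
   hyperparameter search and benchmarked against budget-matched random
   search.

The clinical cohorts such pipelines are evaluated on are access-controlled,
so the package ships a **synthetic phantom generator**: brain-like grayscale
slices whose severity label is carried by geometry (ventricle area grows,
cortical band thins), with texture, shading and noise on top. Every stage,
test and benchmark runs end-to-end on these phantoms on a single CPU. The
networks run on a small built-in numpy layer library with hand-written,
finite-difference-validated backpropagation (`pdfuse.nn`). See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
from pdfuse import pipeline
from pdfuse.mobilenetv3 import Hyperparams

cfg = pipeline.PipelineConfig(
    out_dir="demo", n_per_class=20, image_size=64, seed=4,
    training=Hyperparams(epochs=25, batch_size=16))
report = pipeline.run_pipeline(cfg)
print(report["results"]["evaluation"]["macro"])
```

prints (desk-scale run: 60 training slices at 64×64, 25 epochs)

```
stages run: ['generate', 'preprocess', 'train', 'evaluate']
macro metrics: {
  "accuracy": 0.944,
  "sensitivity": 0.917,
  "specificity": 0.958,
  "precision": 0.933,
  "f_measure": 0.915
}
macro AUC: 1.0
```

i.e. the held-out macro (class-averaged, one-vs-rest) metric suite of the
trained classifier; at the default full scale (300 phantoms at 128×128,
30 epochs) the same call reaches macro accuracy ≥ 0.90. Each script in
`examples/` demonstrates one capability (phantoms, fusion, PCFAN,
classifier, optimizer, pipeline) and prints what the numbers mean. A thin
CLI wraps the same functions:

```bash
pdfuse generate-data --n-per-class 20 --out data --seed 0
pdfuse run-all --seed 1 --out out
pdfuse idmo-bench --function rastrigin --dim 2 --seeds 10
```

Reports are JSON: `report.json` is byte-identical across same-seed re-runs
(timings are kept separately in `timings.json`).

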