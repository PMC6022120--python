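# mff — multi-focus image fusion for plant phenotyping imagery

Low-cost phenotyping cameras have shallow depth of field: in a single frame
of a canola canopy, some seedpods are sharp and others are defocused.
`mff` fuses two or more co-registered photographs of the same scene taken
at different focal depths into one all-in-focus image, and scores fusion
results with the standard no-reference quality metrics QMI, QY and QAB/F.

## Method

Each source image `I_n` is split into a base layer `B_n = I_n * G_{r,σ}`
(Gaussian smoothing) and a detail layer `D_n = I_n − B_n`.  Per-source
weight maps are built from three saliency measures:

* **VS** — visual saliency, the product of a frequency prior (log-Gabor
  band-pass energy over the CIELAB channels), a color prior
  `SC = 1 − exp(−(a'² + b'²)/σ_C²)` on min-max normalized a\*/b\*, and a
  center-bias location prior `SD = exp(−‖k − c‖²/σ_D²)`;
* **GM** — Scharr gradient magnitude of the opponent-space luminance
  `L = 0.06R + 0.63G + 0.27B` (the focus measure);
* **CD** — chrominance (color-distortion) saliency `|M·N|` from the two
  opponent chrominance channels.

The combined weight `W_n = VS^α · GM^β · CD^γ` (defaults α=1, β=0.89,
γ=0.31) is binarized by a per-pixel argmax across sources and refined by
two passes of a **gradient-domain fast guided filter**: the guided filter
`Q_i = ā_k G_i + b̄_k` with a per-pixel edge-aware regularizer
`λ/Γ̂_G(k)` and an edge indicator `γ_k` that together preserve focus
boundaries without halo artifacts, run on nearest-neighbor-subsampled
images (factor `s = 4`) with bilinear coefficient upsampling.  After
morphological cleanup and renormalization, the fused image is
`F = Σ_n W_Bn·B_n + Σ_n W_Dn·D_n`.

Because real multi-focus stacks have no reference image, the package
ships a synthetic-fixture generator (`mff.synthetic`) that applies
complementary regional Gaussian blur to a known sharp truth image, making
recovery measurable (PSNR, focus-mask agreement) alongside the
no-reference metrics.

## Worked example

```python
import numpy as np
from skimage.metrics import peak_signal_noise_ratio as psnr
from mff import default_pairs, evaluate_fusion, fuse

pair = default_pairs(seeds=(1,), shape=(512, 512))[0]
result = fuse(list(pair.sources))

print(f"PSNR vs ground truth: fused {psnr(pair.truth, result.fused, data_range=1.0):.2f} dB, "
      f"sources {[round(psnr(pair.truth, s, data_range=1.0), 2) for s in pair.sources]} dB")
report = evaluate_fusion(pair.sources[0], pair.sources[1], result.fused)
print(f"QMI = {report.qmi:.3f}, QY = {report.qy:.3f}, QAB/F = {report.qabf:.3f}")
mask_hat = result.refined.w_base[0] > 0.5
print(f"focus-mask agreement: {100 * (mask_hat == pair.masks[0]).mean():.2f}%")
```

prints

```
PSNR vs ground truth: fused 45.29 dB, sources [37.12, 36.19] dB
QMI = 0.988, QY = 0.991, QAB/F = 0.801
focus-mask agreement: 98.00%
```

The fused image is ~8 dB closer to the all-in-focus truth than either
half-blurred source; the binarized base-layer weight map reproduces the
true focus partition on 98% of pixels (disagreements sit on the focus
boundary); and all three no-reference metrics are high — QMI near 1 means
roughly half of each source's information survives (2 would be a perfect
copy of both), QY near 1 means local structure is preserved, QAB/F of 0.8
means most source edge information reaches the fused image.

The same operations are available from the shell:

```sh
mff make-fixtures --out fixtures/ --seed 1
mff fuse -i fixtures/source1.tif -i fixtures/source2.tif -o fused.png --save-diagnostics diag/
mff evaluate --source-a fixtures/source1.tif --source-b fixtures/source2.tif --fused fused.png
```

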