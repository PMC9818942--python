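# cwriig

Correlated-weighted RiIG parametric imaging of breast-ultrasound B-mode
frames, with a small six-channel CNN classifier.

## The problem

Benign and malignant breast tumors differ on B-mode ultrasound not only in
shape but in the local statistics of speckle. This package implements a
classification pipeline that makes those statistics explicit instead of
feeding raw pixels to a network:

1. **Multiresolution decomposition.** The B-mode image is decomposed with a
   *contourlet* transform (Laplacian pyramid followed by a directional
   filter bank) or a *curvelet*-style transform (a tight frame from a
   smooth polar-like tiling of the frequency plane). Six sub-bands per
   transform are used downstream: `P2D4, P2D8, P3D8, P3D16, P4D16, P4D32`
   (contourlet pyramid level / direction count) or
   `S2A16, S3A32, S4A32, S5A16, S5A32, S5A64` (curvelet scale / angle
   count).
2. **RiIG δ-mapping.** Sub-band coefficient magnitudes follow the Rician
   inverse Gaussian (RiIG) law — a Rice distribution whose variance is
   mixed over an inverse Gaussian density —

   p(r) = √(2/π) α^{3/2} δ e^{δγ} · r (δ²+r²)^{−3/4} K_{3/2}(α√(δ²+r²)) I₀(βr),

   with steepness α, skewness β (|β| < α), dispersion δ and γ = √(α²−β²).
   A 13 × 13 window slides over each sub-band and the locally fitted δ is
   written at the window center, producing a parametric (CP) image.
   Nakagami *m*-maps and normal-inverse-Gaussian (NIG) α-maps are provided
   for comparison.
3. **Correlated weighting.** Each CP image is weighted by its windowed
   Pearson correlation with the source sub-band, giving the CWCtr-RiIG /
   CWCrv-RiIG images whose pixels lie in [−1, 1].
4. **Classification.** The six weighted sub-band images are resized to
   224 × 224, stacked, and classified by a compact CNN (≈316k parameters,
   combined softmax+sigmoid output activation), or by SVM / KNN / random
   forest on the CNN's 16-dimensional pooled features.

A seeded synthetic-speckle generator (complex circular-Gaussian scatterers,
elliptical lesions with adjustable contrast and margin irregularity,
Gaussian PSF, log compression) makes the whole pipeline testable without
any external data; real PNG/BMP frames can be dropped in instead.

## Worked example

```python
import numpy as np
from cwriig import (SpeckleConfig, simulate_speckle, build_stack,
                    riig_fit, riig_sample, RiIGParams)

# recover RiIG dispersion from a known law
samples = riig_sample(RiIGParams(alpha=2, beta=0, delta=1), 5000, seed=7)
fit = riig_fit(samples)
print(f"delta_hat = {fit.params.delta:.3f}")      # delta_hat = 1.039

# one synthetic frame -> six correlated-weighted channels
image = simulate_speckle(SpeckleConfig(seed=0))
stack = build_stack(image, transform="contourlet", model="riig", stride=4)
print(stack.channels.shape)                        # (6, 224, 224)
print(float(stack.channels.min()), float(stack.channels.max()))
#  -0.350...  0.385...   — correlated weights, bounded in [-1, 1]
```

The printed `delta_hat` is the maximum-likelihood dispersion estimate
(truth 1.0; at n = 5000 the median error across seeds is under 10%). The
stack is the network input: each channel is one sub-band's δ-map weighted
by local correlation with its coefficients, hence the [−1, 1] range.

A full experiment from the shell:

```bash
cwriig simulate --n 20 --out data/        # 40 PNGs + manifest.csv
cwriig run --config configs/desk.yaml     # synthetic 200-image experiment
```

`configs/desk.yaml` holds the desk-scale settings (stride-4 maps, 200
training iterations, minutes on one CPU); `configs/full.yaml` holds the
full-scale settings (stride 1, batch 60, 4000 iterations — hours).
Each run directory contains the resolved config, metrics and confusion
CSVs, the loss trace and the trained checkpoint.

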