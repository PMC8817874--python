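# shearkad

Edge-preserving denoising of ultrasound-style grayscale images, built
around two complementary pieces:

1. a **nonsubsampled shearlet transform (NSST)** — a shift-invariant,
   multiscale, multidirectional Parseval frame built from Meyer-type radial
   and angular frequency windows — whose directional high-frequency
   subbands are **hard thresholded** at θ = 3 times each subband's own
   noise level (the global noise std φ, estimated by the MAD rule
   median(|c|)/0.6745 on the finest-scale coefficients, mapped through the
   filter bank's per-subband RMS gains); and
2. **kernel anisotropic diffusion (KAD)** of the low-frequency band: an
   explicit Perona–Malik-type scheme whose conductivity
   c = exp(−φ_F²‖∇Φ(J)‖²/(4τ²)) measures contrast in the feature space of
   a Gaussian kernel, ‖∇Φ(J)‖_u = [Σ_v (2 − 2F(J_u, J_v))/|N|]^½, with the
   local variance φ_F² and a per-iteration MAD threshold τ jointly gating
   the smoothing.

The package targets speckle-degraded medical ultrasound (the motivating
case: renal stones with acoustic shadows in pediatric kidneys) but is a
general grayscale denoiser.  It ships the comparison baselines (Laplacian-
pyramid nonlinear diffusion, plain NSST thresholding, image-domain KAD,
median filter), PSNR/SSIM/EPI metrics, a fully procedural synthetic corpus
(textured test targets and kidney phantoms with hyperechoic stone +
shadow), and a small clinical-effectiveness calculator, so everything runs
offline with zero downloads.  See `docs/methods.md` for the model details
and design rationale.

## Worked example

```python
import numpy as np
from shearkad import (PhantomSpec, NoiseSpec, make_phantom, add_gaussian_noise,
                      denoise, quality_report)
from shearkad.pipeline import DenoiseConfig

clean = make_phantom(PhantomSpec(size=128))                     # kidney phantom
noisy = add_gaussian_noise(clean, NoiseSpec(sigma=15, seed=0))  # sigma 15 / 255

for method in ("none", "nsst_only", "proposed"):
    out = denoise(noisy, DenoiseConfig(method=method))
    rep = quality_report(clean, out, crop=16)
    print(f"{method:10s}  PSNR {rep.psnr:5.2f} dB  SSIM {rep.ssim:.4f}  EPI {rep.epi:.4f}")
```

prints

```
none        PSNR 24.68 dB  SSIM 0.4086  EPI 0.2187
nsst_only   PSNR 34.23 dB  SSIM 0.9073  EPI 0.7176
proposed    PSNR 35.02 dB  SSIM 0.9166  EPI 0.7818
```

The noisy input sits at 24.7 dB against the clean phantom.  Plain NSST
hard thresholding recovers 34.2 dB; the full pipeline (per-subband
noise-calibrated thresholds plus KAD on the low band) adds another ~0.8 dB
and clearly improves structural similarity and edge preservation (EPI, the
correlation of Laplacian high-pass fields, rewards edges that survive
denoising without blurring).

The same operations are scriptable from the shell:

```bash
shearkad synth phantom --size 128 --out clean.png
shearkad synth noise --kind gaussian --sigma 15 --seed 0 clean.png noisy.png
shearkad denoise run --method proposed noisy.png denoised.png
shearkad metrics compare --crop 16 clean.png denoised.png
shearkad denoise bench --sigmas 5,15,25 --seeds 5 --out results.csv
```

The clinical helper reproduces treatment-effectiveness arithmetic from
stone-outcome counts (disappeared / reduced / unchanged):

```bash
$ shearkad clinical rate --disappeared 22 --reduced 12 --unchanged 4
89.47%
$ shearkad clinical compare --a 25,20,7 --b 22,12,4
fisher: statistic=0.7563 p=0.7544 (not significant at alpha=0.05)
```

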