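"""Full-reference image-quality metrics: PSNR, SSIM and the edge
preservation index (EPI).

PSNR is 10 log10(peak^2 / MSE) in dB with an infinity sentinel at identity.
SSIM uses the canonical windowed formulation: 11-pixel Gaussian window with
sigma = 1.5 and stabilizers C1 = (0.01 peak)^2, C2 = (0.03 peak)^2.
EPI is the Pearson correlation between high-pass filtered (3x3 Laplacian,
mirrored boundary) versions of reference and test, each mean-centered; it is
1 at identity, invariant to constant offsets, and degrades monotonically with
blurring, which is exactly the behavior wanted from an edge-preservation
score for despeckling.

A cropping helper excludes an image border before scoring; frequency-domain
(periodic-boundary) denoisers produce wrap-around artifacts there that say
nothing about interior quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity


@dataclass
class QualityReport:
    """PSNR (dB), SSIM and EPI for one (reference, test) pair."""

    psnr: float
    ssim: float
    epi: float


def crop_border(img: np.ndarray, width: int) -> np.ndarray:
    """Drop a ``width``-pixel border (no-op for width <= 0)."""
    if width <= 0:
        return img
    if 2 * width >= min(img.shape):
        raise ValueError("crop width leaves no pixels")
    return img[width:-width, width:-width]


def auto_crop_width(shape: tuple[int, int], n_scales: int = 3) -> int:
    """Default metric crop: grows with decomposition depth, capped at 1/8 dim."""
    return min(2 ** (n_scales + 1), min(shape) // 8)


def psnr(ref: np.ndarray, test: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; np.inf for identical images."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("shape mismatch")
    if peak <= 0:
        raise ValueError("peak must be > 0")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return np.inf
    return 10.0 * np.log10(peak**2 / mse)


def ssim(ref: np.ndarray, test: np.ndarray, peak: float = 255.0) -> float:
    """Mean structural similarity, Gaussian 11x11 window (sigma 1.5)."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("shape mismatch")
    if min(ref.shape) < 11:
        raise ValueError("images too small for the 11-pixel SSIM window")
    return float(
        structural_similarity(
            ref,
            test,
            data_range=peak,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def epi(ref: np.ndarray, test: np.ndarray) -> float:
    """Edge preservation index: correlation of Laplacian high-pass fields.

    Returns NaN when either high-pass field has zero variance (edge content
    undefined).
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("shape mismatch")
    hp_ref = ndimage.laplace(ref, mode="reflect")
    hp_test = ndimage.laplace(test, mode="reflect")
    hp_ref = hp_ref - hp_ref.mean()
    hp_test = hp_test - hp_test.mean()
    denom = np.sqrt(np.sum(hp_ref**2) * np.sum(hp_test**2))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(hp_ref * hp_test) / denom)


def quality_report(
    ref: np.ndarray,
    test: np.ndarray,
    peak: float = 255.0,
    crop: int = 0,
) -> QualityReport:
    """All three metrics for one pair, optionally after border cropping."""
    ref = crop_border(np.asarray(ref, dtype=float), crop)
    test = crop_border(np.asarray(test, dtype=float), crop)
    return QualityReport(psnr=psnr(ref, test, peak), ssim=ssim(ref, test, peak), epi=epi(ref, test))
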