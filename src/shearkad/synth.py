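"""Synthetic test inputs: procedural natural-image stand-ins, ultrasound-like
kidney phantoms, and the two noise models used throughout the benchmarks.

Everything here is a pure function of its spec (seed included): repeated
calls are bit-identical, so the whole test corpus is generated at run time
and nothing needs to be downloaded or shipped.

Two input families are emulated:

* a deterministic textured grayscale target with smooth gradients, step
  edges, discs, and periodic stripes, standing in for the classic
  Lena/Barbara 512 x 512 test pair (which is not redistributable); the
  stripes stress edge preservation the way Barbara's textiles do, and the
  quantitative protocol corrupts it with additive Gaussian white noise at
  standard deviations 5, 15, and 25 on the 0-255 scale;
* a kidney phantom with an elliptical organ, a hyperechoic (bright) stone
  disc and the hypoechoic acoustic shadow column beneath it, optionally
  corrupted with unit-mean multiplicative speckle (a fully-developed speckle
  approximation using a Gamma multiplier).

Intensities are floating point on the 0-255 scale; clipping to the valid
range happens only at I/O boundaries, never between pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class NoiseSpec:
    """Noise model: additive Gaussian or unit-mean multiplicative speckle.

    sigma is on the 0-255 intensity scale; for speckle it sets the multiplier
    std to sigma / 255.
    """

    kind: str = "gaussian_additive"
    sigma: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_additive", "speckle_multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class PhantomSpec:
    """Geometry and echogenicity of the kidney phantom.

    Requires stone_level > organ_level > shadow_level (a urinary stone is
    hyperechoic; its acoustic shadow is hypoechoic).
    """

    size: int = 128
    background_level: float = 40.0
    organ_level: float = 110.0
    stone_level: float = 230.0
    shadow_level: float = 25.0
    stone_center: tuple[int, int] | None = None
    stone_radius: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 64 <= self.size <= 1024:
            raise ValueError("size must be in [64, 1024]")
        if not (self.stone_level > self.organ_level > self.shadow_level):
            raise ValueError("need stone_level > organ_level > shadow_level")
        if self.stone_center is None:
            self.stone_center = (int(self.size * 0.40), int(self.size * 0.55))
        if self.stone_radius is None:
            self.stone_radius = max(3, self.size // 16)
        r, c = self.stone_center
        rad = self.stone_radius
        if not (rad <= r < self.size - rad and rad <= c < self.size - rad):
            raise ValueError("stone geometry outside image bounds")


def add_gaussian_noise(img: np.ndarray, spec: NoiseSpec, clip: bool = True) -> np.ndarray:
    """Additive i.i.d. N(0, sigma^2) pixel noise, clipped to [0, 255]."""
    if spec.kind != "gaussian_additive":
        raise ValueError("spec.kind must be 'gaussian_additive'")
    img = np.asarray(img, dtype=float)
    rng = np.random.default_rng(spec.seed)
    noisy = img + rng.normal(0.0, spec.sigma, size=img.shape)
    return np.clip(noisy, 0.0, 255.0) if clip else noisy


def add_speckle_noise(img: np.ndarray, spec: NoiseSpec, clip: bool = True) -> np.ndarray:
    """Multiplicative unit-mean Gamma speckle: out = img * n, E[n] = 1.

    The Gamma shape k is chosen so std(n) = sigma / 255 (k = 1/std^2,
    scale 1/k).  sigma = 0 degenerates to the identity.
    """
    if spec.kind != "speckle_multiplicative":
        raise ValueError("spec.kind must be 'speckle_multiplicative'")
    img = np.asarray(img, dtype=float)
    if spec.sigma == 0:
        return img.copy()
    rel_std = spec.sigma / 255.0
    shape = 1.0 / rel_std**2
    rng = np.random.default_rng(spec.seed)
    multiplier = rng.gamma(shape, 1.0 / shape, size=img.shape)
    noisy = img * multiplier
    return np.clip(noisy, 0.0, 255.0) if clip else noisy


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic noiseless kidney phantom.

    An elliptical organ on a dark background, a bright stone disc inside it,
    and a darker acoustic-shadow column extending from the stone to the
    bottom edge.  Region edges are slightly smoothed (2-pixel cosine ramp) so
    the image has realistic, not aliased, boundaries.
    """
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)

    def soft_mask(signed_dist: np.ndarray, ramp: float = 2.0) -> np.ndarray:
        # 1 inside (signed_dist <= 0), 0 outside, cosine ramp across the edge
        t = np.clip(signed_dist / ramp + 0.5, 0.0, 1.0)
        return 0.5 * (1.0 + np.cos(np.pi * t))

    img = np.full((n, n), spec.background_level)

    cy, cx = n * 0.5, n * 0.5
    a, b = n * 0.42, n * 0.30  # organ semi-axes
    organ_dist = np.sqrt(((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2) - 1.0
    organ = soft_mask(organ_dist * min(a, b))
    img = img + (spec.organ_level - spec.background_level) * organ

    sy, sx = spec.stone_center
    shadow_dist = np.maximum(np.abs(xx - sx) - spec.stone_radius, sy - yy)
    shadow = soft_mask(shadow_dist) * organ
    img = img + (spec.shadow_level - spec.organ_level) * shadow

    stone_dist = np.sqrt((yy - sy) ** 2 + (xx - sx) ** 2) - spec.stone_radius
    stone = soft_mask(stone_dist)
    img = img + (spec.stone_level - img) * stone
    return img


def phantom_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boolean interior masks of the stone, shadow and plain-organ regions."""
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    sy, sx = spec.stone_center
    stone = (yy - sy) ** 2 + (xx - sx) ** 2 <= (spec.stone_radius - 2) ** 2
    cy, cx = n * 0.5, n * 0.5
    a, b = n * 0.42, n * 0.30
    organ_all = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 0.9**2
    shadow = (
        organ_all
        & (np.abs(xx - sx) <= spec.stone_radius - 2)
        & (yy >= sy + spec.stone_radius + 2)
    )
    organ = organ_all & ~stone & ~shadow & (np.abs(xx - sx) > spec.stone_radius + 2)
    return {"stone": stone, "shadow": shadow, "organ": organ}


def make_natural_test_image(size: int = 512, seed: int = 0) -> np.ndarray:
    """Deterministic textured target with smooth areas, edges and stripes.

    Composition: a diagonal illumination gradient; a high-contrast step edge
    (>= 64 levels); two discs of different brightness; a patch of periodic
    diagonal stripes (the classic edge-preservation stressor); and a faint
    smooth random texture so no region is perfectly flat.  Dynamic range
    spans well over half the 0-255 scale.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    n = size
    yy, xx = np.mgrid[0:n, 0:n].astype(float) / n
    img = 60.0 + 120.0 * (0.5 * xx + 0.5 * yy)  # smooth gradient 60..180

    img[(yy > 0.55) & (xx < 0.45)] += 70.0  # step edge, contrast 70

    d1 = np.sqrt((yy - 0.25) ** 2 + (xx - 0.70) ** 2)
    img = np.where(d1 < 0.12, 220.0, img)
    d2 = np.sqrt((yy - 0.75) ** 2 + (xx - 0.75) ** 2)
    img = np.where(d2 < 0.10, 30.0, img)

    stripes = (yy < 0.45) & (xx < 0.40)
    img[stripes] = 120.0 + 55.0 * np.sin(2 * np.pi * 12 * (xx + 0.6 * yy))[stripes]

    rng = np.random.default_rng(seed)
    k = max(4, n // 32)
    coarse = rng.normal(0.0, 1.0, size=(k, k))
    fy = np.linspace(0, k - 1, n)
    fx = np.linspace(0, k - 1, n)
    texture = _bilinear_upsample(coarse, fy, fx)
    img = img + 6.0 * texture
    return np.clip(img, 0.0, 255.0)


def _bilinear_upsample(grid: np.ndarray, fy: np.ndarray, fx: np.ndarray) -> np.ndarray:
    y0 = np.clip(np.floor(fy).astype(int), 0, grid.shape[0] - 2)
    x0 = np.clip(np.floor(fx).astype(int), 0, grid.shape[1] - 2)
    wy = (fy - y0)[:, None]
    wx = (fx - x0)[None, :]
    g = grid
    return (
        g[np.ix_(y0, x0)] * (1 - wy) * (1 - wx)
        + g[np.ix_(y0 + 1, x0)] * wy * (1 - wx)
        + g[np.ix_(y0, x0 + 1)] * (1 - wy) * wx
        + g[np.ix_(y0 + 1, x0 + 1)] * wy * wx
    )
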