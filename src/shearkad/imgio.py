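"""Grayscale image I/O on the floating-point 0-255 working scale.

PNG/TIFF via imageio; single-frame DICOM via pydicom when available.  Images
are held internally as float64 on the 0-255 scale regardless of the on-disk
bit depth; clipping and quantization happen only here, at the I/O boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import imageio.v3 as iio


def load_gray(path: str | Path) -> np.ndarray:
    """Read an image as 2D float64 on the 0-255 scale.

    Color inputs are converted with the Rec. 601 luma weights; 16-bit inputs
    are rescaled to 0-255.  ``.dcm`` files are read with pydicom and reduced
    to their first frame.
    """
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        if arr.ndim == 3:
            arr = arr[0]
    else:
        arr = iio.imread(path).astype(float)
        if arr.ndim == 3:
            arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    peak = arr.max()
    if peak > 255:
        arr = arr * (255.0 / peak)
    return arr


def save_gray(path: str | Path, img: np.ndarray, bit_depth: int = 8) -> None:
    """Write a 0-255 float image as 8- or 16-bit grayscale PNG/TIFF."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    img = np.clip(np.asarray(img, dtype=float), 0.0, 255.0)
    if bit_depth == 8:
        data = np.round(img).astype(np.uint8)
    else:
        data = np.round(img * (65535.0 / 255.0)).astype(np.uint16)
    iio.imwrite(Path(path), data)
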