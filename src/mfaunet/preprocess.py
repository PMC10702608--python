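"""Fundus photograph preprocessing.

Raw fundus photographs suffer from uneven illumination and low vessel
contrast.  The pipeline applied before patch extraction is:

1. optional crop to the bounding box of the circular field of view (FOV),
2. NTSC grayscale conversion ``Gray = 0.299 R + 0.587 G + 0.114 B``,
3. gamma correction ``out = in ** (1/gamma)`` (gamma 1.2 brightens the
   darker retina periphery),
4. contrast-limited adaptive histogram equalisation (CLAHE) to equalise
   vessel/background contrast locally.

Images are held as float rasters in [0, 1]; uint8 only appears at file I/O
and inside the histogram equalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure


@dataclass
class PreprocessConfig:
    """Knobs of the enhancement pipeline.

    ``clahe_clip_limit`` uses the OpenCV-style convention (typical values
    1-4); it is divided by 256 internally to obtain the normalised clip
    limit the scikit-image implementation expects.
    """

    gamma: float = 1.2
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    crop_to_fov: bool = False
    apply_gamma: bool = True
    apply_clahe: bool = True

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if min(self.clahe_tile_grid) < 1:
            raise ValueError("CLAHE tile grid dims must be >= 1")
        if self.clahe_clip_limit <= 0:
            raise ValueError("CLAHE clip limit must be positive")


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB raster, got shape {img.shape}")
    return img


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """NTSC luma conversion, returned as float64 in [0, 1]."""
    img = _check_rgb(img).astype(np.float64)
    gray = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    return np.clip(gray / 255.0, 0.0, 1.0)


def gamma_correct(img: np.ndarray, cfg: PreprocessConfig | None = None,
                  gamma: float | None = None) -> np.ndarray:
    """Power-law remap ``out = in ** (1/gamma)``; gamma > 1 brightens."""
    if gamma is None:
        gamma = (cfg or PreprocessConfig()).gamma
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    img = np.asarray(img, dtype=np.float64)
    return np.power(np.clip(img, 0.0, 1.0), 1.0 / gamma)


def clahe_enhance(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on [0, 1] rasters.

    The input is quantised to uint8, equalised tile-wise, and rescaled to
    [0, 1].  A constant image has a flat histogram and is returned as-is.
    """
    cfg = cfg or PreprocessConfig()
    img = np.asarray(img, dtype=np.float64)
    if img.min() == img.max():
        return img.copy()
    u8 = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    ty, tx = cfg.clahe_tile_grid
    kernel = (max(1, u8.shape[0] // ty), max(1, u8.shape[1] // tx))
    out = exposure.equalize_adapthist(
        u8, kernel_size=kernel, clip_limit=cfg.clahe_clip_limit / 256.0)
    return np.clip(out, 0.0, 1.0)


def fov_bounding_box(img: np.ndarray, fov: np.ndarray | None) -> tuple[int, int, int, int]:
    """(row0, row1, col0, col1) half-open bounding box of the field of view.

    Without an explicit FOV mask the red channel is thresholded at 20/255
    and the largest connected component is taken.
    """
    if fov is None:
        red = _check_rgb(img)[..., 0]
        mask = red > 20
        lab, n = ndimage.label(mask)
        if n == 0:
            return 0, img.shape[0], 0, img.shape[1]
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    else:
        mask = np.asarray(fov).astype(bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def preprocess(img: np.ndarray, cfg: PreprocessConfig | None = None,
               fov: np.ndarray | None = None) -> np.ndarray:
    """Full pipeline: (crop) -> grayscale -> gamma -> CLAHE."""
    cfg = cfg or PreprocessConfig()
    img = _check_rgb(img)
    if cfg.crop_to_fov:
        r0, r1, c0, c1 = fov_bounding_box(img, fov)
        img = img[r0:r1, c0:c1]
    gray = rgb_to_gray(img)
    if cfg.apply_gamma:
        gray = gamma_correct(gray, cfg)
    if cfg.apply_clahe:
        gray = clahe_enhance(gray, cfg)
    return gray
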