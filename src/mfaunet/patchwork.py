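"""Overlapping-patch bookkeeping: planning, extraction, augmentation, stitching.

Whole fundus images are too large (and too few) to train on directly, so
training operates on heavily overlapping square windows.  Coordinates are
0-based and row-major; a window at origin (r, c) covers the half-open block
``[r, r+w) x [c, c+w)``.  At inference time an *edge-complete* grid covers
every pixel and the per-pixel prediction is the mean over all covering
windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize


@dataclass
class PatchGrid:
    window: int
    stride: int
    origins: list[tuple[int, int]]
    image_dims: tuple[int, int]
    edge_complete: bool

    def __len__(self):
        return len(self.origins)


@dataclass
class PatchSet:
    grid: PatchGrid
    images: np.ndarray                      # (n, w, w)
    masks: np.ndarray | None = None         # (n, w, w) or None

    def __len__(self):
        return len(self.grid.origins)


def _axis_origins(dim: int, window: int, stride: int, edge_complete: bool):
    last = dim - window
    xs = list(range(0, last + 1, stride))
    if edge_complete and xs[-1] != last:
        xs.append(last)
    return xs


def plan_grid(height: int, width: int, window: int = 128, stride: int = 15,
              edge_complete: bool = False) -> PatchGrid:
    """Regular row-major grid of window origins over an HxW image."""
    if window > height or window > width:
        raise ValueError(f"window {window} exceeds image dims {(height, width)}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rows = _axis_origins(height, window, stride, edge_complete)
    cols = _axis_origins(width, window, stride, edge_complete)
    origins = [(r, c) for r in rows for c in cols]
    return PatchGrid(window, stride, origins, (height, width), edge_complete)


def overlap_percent(window: int, stride: int) -> float:
    """Linear overlap between adjacent windows, in percent of the window."""
    if stride > window:
        return 0.0
    return 100.0 * (window - stride) / window


def extract_patches(img: np.ndarray, mask: np.ndarray | None,
                    grid: PatchGrid) -> PatchSet:
    """Cut the grid's windows out of an image (and aligned mask)."""
    img = np.asarray(img)
    if img.shape[:2] != grid.image_dims:
        raise ValueError(f"grid planned for {grid.image_dims}, image is {img.shape[:2]}")
    if mask is not None and np.asarray(mask).shape[:2] != grid.image_dims:
        raise ValueError("mask dims differ from grid dims")
    w = grid.window
    imgs = np.stack([img[r:r + w, c:c + w] for r, c in grid.origins])
    msks = None
    if mask is not None:
        mask = np.asarray(mask)
        msks = np.stack([mask[r:r + w, c:c + w] for r, c in grid.origins])
    return PatchSet(grid, imgs, msks)


@dataclass
class AugmentParams:
    """One draw of the random patch transform (fully determined by a seed)."""
    hflip: bool = False
    vflip: bool = False
    angle_deg: float = 0.0
    crop_frac: float = 1.0
    crop_r: float = 0.0     # fractional position of the crop inside the patch
    crop_c: float = 0.0


def draw_augment_params(rng: np.random.Generator) -> AugmentParams:
    return AugmentParams(
        hflip=bool(rng.random() < 0.5),
        vflip=bool(rng.random() < 0.5),
        angle_deg=float(rng.uniform(-180.0, 180.0)),
        crop_frac=float(rng.uniform(0.8, 1.0)),
        crop_r=float(rng.random()),
        crop_c=float(rng.random()),
    )


def apply_augment(img: np.ndarray, mask: np.ndarray | None,
                  params: AugmentParams):
    """Apply one transform draw identically to an image patch and its mask.

    The image is resampled bilinearly, the mask with nearest neighbour so
    it stays binary.
    """
    im = np.asarray(img, dtype=np.float64)
    mk = None if mask is None else np.asarray(mask)
    mk_dtype = None if mk is None else mk.dtype
    if params.hflip:
        im = im[:, ::-1]
        mk = None if mk is None else mk[:, ::-1]
    if params.vflip:
        im = im[::-1]
        mk = None if mk is None else mk[::-1]
    if params.angle_deg != 0.0:
        im = ndimage.rotate(im, params.angle_deg, reshape=False, order=1,
                            mode="reflect")
        if mk is not None:
            mk = ndimage.rotate(mk, params.angle_deg, reshape=False, order=0,
                                mode="reflect")
    if params.crop_frac < 1.0:
        h, w = im.shape
        ch = max(1, int(round(params.crop_frac * h)))
        cw = max(1, int(round(params.crop_frac * w)))
        r0 = int(round(params.crop_r * (h - ch)))
        c0 = int(round(params.crop_c * (w - cw)))
        im = _sk_resize(im[r0:r0 + ch, c0:c0 + cw], (h, w), order=1,
                        anti_aliasing=False)
        if mk is not None:
            mk = _sk_resize(mk[r0:r0 + ch, c0:c0 + cw], (h, w), order=0,
                            anti_aliasing=False, preserve_range=True)
    if mk is not None:
        mk = (np.asarray(mk) > 0.5).astype(mk_dtype)
    return np.clip(im, 0.0, 1.0), mk


def augment_patch(img: np.ndarray, mask: np.ndarray | None, seed: int):
    """Seeded random flip / rotation / crop-and-resize of a patch pair."""
    params = draw_augment_params(np.random.default_rng(seed))
    return apply_augment(img, mask, params)


def stitch(prob_patches: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Reassemble per-patch probability maps by per-pixel averaging.

    Accumulation runs in float64; because every pixel's contributions are
    divided by their exact integer count, stitching patches cut from a
    single float32 map reproduces that map exactly.
    """
    prob_patches = np.asarray(prob_patches, dtype=np.float64)
    h, wd = grid.image_dims
    w = grid.window
    acc = np.zeros((h, wd))
    cnt = np.zeros((h, wd))
    for patch, (r, c) in zip(prob_patches, grid.origins):
        acc[r:r + w, c:c + w] += patch
        cnt[r:r + w, c:c + w] += 1.0
    if np.any(cnt == 0):
        raise ValueError("grid does not cover every pixel; plan with "
                         "edge_complete=True for stitching")
    return (acc / cnt).astype(np.float32)
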