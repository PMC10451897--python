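"""Fundus-image preprocessing chain.

The chain mirrors standard retinal-photograph preparation for lesion
classifiers: (1) crop away the black camera border around the circular
retinal disc, (2) contrast-limited adaptive histogram equalization
(CLAHE) on the luma channel to flatten the center-to-edge illumination
gradient of the concave retina, (3) Gaussian background subtraction
(unsharp enhancement) ``x_tilde = clip(kappa * (x - G_sigma * x) +
delta)`` which removes slowly-varying illumination and recenters
intensities at ``delta``, and (4) minority-class balancing by randomly
transformed copies of the under-represented (abnormal) class only.

CLAHE follows the OpenCV convention: ``clip_limit`` is a multiple of
the mean histogram bin count of a tile, the clipped excess is
redistributed uniformly, and per-tile lookup tables are blended
bilinearly between tile centers.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import AffineTransform, warp

from .data import FundusSample
from .specs import PreprocessConfig

__all__ = [
    "UnusableImageError",
    "remove_borders",
    "clahe_enhance",
    "gaussian_enhance",
    "augment_minority",
    "preprocess_image",
    "AUGMENT_OPS",
]


class UnusableImageError(ValueError):
    """Raised when an image contains no foreground at all.

    Stands in for manual quality screening: an image whose every pixel
    sits below the background threshold carries no retinal structure.
    """


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("expected a nonempty H x W x 3 image")
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        img = img.astype(np.uint8)
    return img


# ----------------------------------------------------------------------
# border removal
# ----------------------------------------------------------------------

def remove_borders(img: np.ndarray, threshold: int = 10) -> np.ndarray:
    """Minimal axis-aligned crop containing every above-threshold pixel.

    A pixel is foreground when its maximum channel intensity exceeds
    ``threshold``.  Idempotent by construction.
    """
    img = _check_image(img)
    mask = img.max(axis=2) > threshold
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise UnusableImageError("image is entirely background; cannot crop")
    return img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]


# ----------------------------------------------------------------------
# CLAHE
# ----------------------------------------------------------------------

def _rgb_to_ycbcr(img: np.ndarray) -> np.ndarray:
    r, g, b = img[..., 0].astype(np.float64), img[..., 1].astype(np.float64), \
        img[..., 2].astype(np.float64)
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return np.stack([y, cb, cr], axis=-1)


def _ycbcr_to_rgb(ycc: np.ndarray) -> np.ndarray:
    y, cb, cr = ycc[..., 0], ycc[..., 1] - 128.0, ycc[..., 2] - 128.0
    r = y + 1.402 * cr
    g = y - 0.344136 * cb - 0.714136 * cr
    b = y + 1.772 * cb
    return np.clip(np.rint(np.stack([r, g, b], axis=-1)), 0, 255).astype(np.uint8)


def _clahe_luts(channel: np.ndarray, clip_limit: float, grid: int) -> np.ndarray:
    """Per-tile clipped-equalization lookup tables, shape (grid, grid, 256)."""
    h, w = channel.shape
    row_edges = np.linspace(0, h, grid + 1).astype(int)
    col_edges = np.linspace(0, w, grid + 1).astype(int)
    luts = np.empty((grid, grid, 256), dtype=np.float64)
    for i in range(grid):
        for j in range(grid):
            tile = channel[row_edges[i]:row_edges[i + 1],
                           col_edges[j]:col_edges[j + 1]]
            area = tile.size
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.int64)
            clip = max(1, int(clip_limit * area / 256.0))
            excess = int(np.maximum(hist - clip, 0).sum())
            hist = np.minimum(hist, clip)
            hist += excess // 256
            hist[: excess % 256] += 1  # residual spread over the lowest bins
            cdf = np.cumsum(hist)
            luts[i, j] = np.rint(cdf * (255.0 / area))
    return luts


def clahe_enhance(img: np.ndarray, clip_limit: float = 7.0,
                  tile_grid: int = 6) -> np.ndarray:
    """CLAHE on the luma channel of a YCbCr decomposition.

    ``clip_limit`` caps each tile histogram bin at ``clip_limit`` times
    the tile's mean bin count; the clipped mass is redistributed
    uniformly.  Tile mappings are blended bilinearly between tile
    centers, with clamping at the image border.
    """
    img = _check_image(img)
    if clip_limit <= 0 or tile_grid < 1:
        raise ValueError("clip_limit must be > 0 and tile_grid >= 1")
    h, w = img.shape[:2]
    if h < tile_grid or w < tile_grid:
        raise ValueError("tile grid finer than the image itself")
    ycc = _rgb_to_ycbcr(img)
    luma = np.clip(np.rint(ycc[..., 0]), 0, 255).astype(np.uint8)

    luts = _clahe_luts(luma, clip_limit, tile_grid)
    row_edges = np.linspace(0, h, tile_grid + 1)
    col_edges = np.linspace(0, w, tile_grid + 1)
    cy = (row_edges[:-1] + row_edges[1:]) / 2.0
    cx = (col_edges[:-1] + col_edges[1:]) / 2.0

    def _coords(pos: np.ndarray, centers: np.ndarray):
        idx = np.searchsorted(centers, pos) - 1
        i0 = np.clip(idx, 0, len(centers) - 1)
        i1 = np.clip(idx + 1, 0, len(centers) - 1)
        denom = centers[i1] - centers[i0]
        frac = np.where(denom > 0, (pos - centers[i0]) / np.where(denom == 0, 1,
                                                                  denom), 0.0)
        return i0, i1, np.clip(frac, 0.0, 1.0)

    r0, r1, fy = _coords(np.arange(h) + 0.5, cy)
    c0, c1, fx = _coords(np.arange(w) + 0.5, cx)
    fy = fy[:, None]
    fx = fx[None, :]
    v = luma
    top = (1 - fx) * luts[r0[:, None], c0[None, :], v] + fx * luts[
        r0[:, None], c1[None, :], v]
    bot = (1 - fx) * luts[r1[:, None], c0[None, :], v] + fx * luts[
        r1[:, None], c1[None, :], v]
    new_luma = (1 - fy) * top + fy * bot

    ycc_out = ycc.copy()
    ycc_out[..., 0] = new_luma
    return _ycbcr_to_rgb(ycc_out)


# ----------------------------------------------------------------------
# Gaussian background subtraction
# ----------------------------------------------------------------------

def gaussian_enhance(img: np.ndarray, kappa: float = 4.0, sigma: float = 10.0,
                     delta: float = 128.0) -> np.ndarray:
    """Unsharp enhancement: clip(kappa * (x - blur(x; sigma)) + delta).

    The blur is a per-channel Gaussian with reflective boundaries, so
    the operator commutes with horizontal/vertical flips.
    """
    img = _check_image(img)
    for name, val in (("kappa", kappa), ("sigma", sigma), ("delta", delta)):
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = img.astype(np.float64)
    blur = gaussian_filter(x, sigma=(sigma, sigma, 0.0))
    out = kappa * (x - blur) + delta
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def preprocess_image(img: np.ndarray, cfg: PreprocessConfig | None = None,
                     quality_hook=None) -> np.ndarray:
    """Full chain: border crop -> CLAHE -> Gaussian enhancement.

    The blur scale adapts to the image: sigma = crop width / sigma_divisor.

    ``quality_hook``, if given, is called with the raw image before any
    processing and should raise :class:`UnusableImageError` to reject
    it — the plug-in point for image-quality screening, which is
    otherwise limited to the all-background check in
    :func:`remove_borders`.
    """
    cfg = cfg or PreprocessConfig()
    if quality_hook is not None:
        quality_hook(img)
    img = remove_borders(img, cfg.background_threshold)
    img = clahe_enhance(img, cfg.clip_limit, cfg.tile_grid)
    sigma = img.shape[1] / cfg.sigma_divisor
    return gaussian_enhance(img, cfg.kappa, sigma, cfg.delta)


# ----------------------------------------------------------------------
# minority-class balancing augmentation
# ----------------------------------------------------------------------

def _warp_uint8(img: np.ndarray, tform: AffineTransform) -> np.ndarray:
    out = warp(img.astype(np.float64) / 255.0, tform.inverse, order=1,
               mode="constant", cval=0.0, preserve_range=True)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def _centered(img: np.ndarray, tform: AffineTransform) -> AffineTransform:
    h, w = img.shape[:2]
    shift = AffineTransform(translation=(-w / 2, -h / 2))
    unshift = AffineTransform(translation=(w / 2, h / 2))
    return AffineTransform(matrix=unshift.params @ tform.params @ shift.params)


def _op_rotate(img, rng):
    angle = np.deg2rad(rng.uniform(-30.0, 30.0))
    return _warp_uint8(img, _centered(img, AffineTransform(rotation=angle)))


def _op_hflip(img, rng):
    return img[:, ::-1].copy()


def _op_vflip(img, rng):
    return img[::-1, :].copy()


def _op_scale(img, rng):
    s = rng.uniform(0.9, 1.1)
    return _warp_uint8(img, _centered(img, AffineTransform(scale=(s, s))))


def _op_hshift(img, rng):
    dx = rng.uniform(-0.1, 0.1) * img.shape[1]
    return _warp_uint8(img, AffineTransform(translation=(dx, 0)))


def _op_vshift(img, rng):
    dy = rng.uniform(-0.1, 0.1) * img.shape[0]
    return _warp_uint8(img, AffineTransform(translation=(0, dy)))


def _op_shear(img, rng):
    sh = np.deg2rad(rng.uniform(-10.0, 10.0))
    return _warp_uint8(img, _centered(img, AffineTransform(shear=sh)))


def _op_fill(img, rng):
    # random small crop filled back to size (zoom-with-fill)
    h, w = img.shape[:2]
    fy, fx = rng.uniform(0.05, 0.1), rng.uniform(0.05, 0.1)
    out = np.zeros_like(img)
    y0, x0 = int(fy * h), int(fx * w)
    out[y0:h, x0:w] = img[: h - y0, : w - x0]
    return out


AUGMENT_OPS = {
    "rotate": _op_rotate,
    "hflip": _op_hflip,
    "vflip": _op_vflip,
    "scale": _op_scale,
    "hshift": _op_hshift,
    "vshift": _op_vshift,
    "shear": _op_shear,
    "fill": _op_fill,
}


def augment_minority(samples: list[FundusSample], seed: int = 0,
                     op_set: tuple[str, ...] | None = None
                     ) -> list[FundusSample]:
    """Upsample the minority class with transformed copies until 1:1.

    Only the under-represented class is augmented; originals are kept
    untouched and returned first.  Deterministic under ``seed``.
    """
    if op_set is None:
        op_set = tuple(AUGMENT_OPS)
    unknown = set(op_set) - set(AUGMENT_OPS)
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    labels = np.array([s.label for s in samples])
    n0, n1 = int((labels == 0).sum()), int((labels == 1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to balance")
    if n0 == n1:
        return list(samples)
    minority = 0 if n0 < n1 else 1
    pool = [s for s in samples if s.label == minority]
    deficit = abs(n0 - n1)
    rng = np.random.default_rng(seed)
    out = list(samples)
    for k in range(deficit):
        src = pool[k % len(pool)]
        ops = [name for name in op_set if rng.random() < 0.5]
        if not ops:
            ops = [op_set[int(rng.integers(len(op_set)))]]
        img = src.image
        for name in ops:
            img = AUGMENT_OPS[name](img, rng)
        out.append(FundusSample(image=img, label=minority,
                                path=None, seed=seed + k))
    return out
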