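"""Synthetic fundus-like image generator for the two-class reflex task.

Each image is a circular orange-tinted retinal disc on a black
background, crossed by dark curvilinear vessels (random quadratic
Bezier curves radiating from the disc center region).  Class-1 images
additionally carry a bright copper-tinted central stripe along a
random "arterial" subset of vessels — a cartoon of the widened central
light reflex of arteriolosclerosis.  Both classes get per-image global
brightness jitter larger than the mean-intensity shift the stripes
cause, so the classes are not separable by global brightness alone.

All randomness is driven by ``(cfg.seed, sample_seed)``; the vessel
geometry is drawn identically for both classes, so the class-0 and
class-1 images of the same sample seed differ only by the reflex
stripes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .data import FundusSample, save_image, write_manifest
from .specs import SynthConfig

__all__ = ["generate_sample", "generate_sample_with_geometry",
           "generate_dataset", "generate_arrays", "centerline_mean_intensity"]

_VESSEL_COLOR = np.array([60.0, 26.0, 22.0])
# quadrant -> (theta_lo, theta_hi) in image coords (y down): 0 TL, 1 TR, 2 BL, 3 BR
_QUADRANT_ANGLES = {
    0: (-np.pi + 0.15, -np.pi / 2 - 0.15),
    1: (-np.pi / 2 + 0.15, -0.15),
    2: (np.pi / 2 + 0.15, np.pi - 0.15),
    3: (0.15, np.pi / 2 - 0.15),
}


def _bezier(p0, p1, p2, n_pts: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _vessel_geometry(rng, center, radius, theta_range=None, n_pts=240):
    lo, hi = theta_range if theta_range else (-np.pi, np.pi)
    th0 = rng.uniform(lo, hi)
    th1 = np.clip(th0 + rng.uniform(-0.6, 0.6), lo, hi) if theta_range \
        else th0 + rng.uniform(-0.9, 0.9)
    r0 = rng.uniform(0.25 if theta_range else 0.05, 0.3) * radius
    r1 = rng.uniform(0.82, 0.93) * radius
    p0 = center + r0 * np.array([np.cos(th0), np.sin(th0)])
    p2 = center + r1 * np.array([np.cos(th1), np.sin(th1)])
    thm, rm = (th0 + th1) / 2.0, (r0 + r1) / 2.0
    pm = center + rm * np.array([np.cos(thm), np.sin(thm)])
    perp = rng.uniform(-0.12 if theta_range else -0.25,
                       0.12 if theta_range else 0.25) * radius
    p1 = pm + perp * np.array([-np.sin(thm), np.cos(thm)])
    return _bezier(p0, p1, p2, n_pts)  # (n_pts, 2) as (x, y)


def _stamp(img, pts, width, color, mode, quad_mask=None):
    """Blend a curve of given width into img; soft 1-px anti-aliased edge."""
    h, w_img = img.shape[:2]
    tree = cKDTree(pts)
    x0 = max(0, int(pts[:, 0].min() - width))
    x1 = min(w_img, int(pts[:, 0].max() + width) + 2)
    y0 = max(0, int(pts[:, 1].min() - width))
    y1 = min(h, int(pts[:, 1].max() + width) + 2)
    if x1 <= x0 or y1 <= y0:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    grid = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
    d, _ = tree.query(grid, k=1)
    cov = np.clip(width / 2.0 + 0.5 - d, 0.0, 1.0).reshape(yy.shape)
    if quad_mask is not None:
        cov = cov * quad_mask[y0:y1, x0:x1]
    patch = img[y0:y1, x0:x1]
    if mode == "blend":
        patch[:] = patch * (1 - 0.85 * cov[..., None]) + \
            0.85 * cov[..., None] * color
    else:  # additive (reflex stripe)
        patch[:] = patch + cov[..., None] * color


def generate_sample_with_geometry(cls: int, cfg: SynthConfig, sample_seed: int,
                                  reflex_quadrant: int | None = None
                                  ) -> tuple[FundusSample, dict]:
    """Generate one image plus the geometry the renderer actually used."""
    if cls not in (0, 1):
        raise ValueError("class must be 0 or 1")
    rng = np.random.default_rng([cfg.seed, sample_seed])
    s = cfg.image_size
    center = np.array([s / 2.0, s / 2.0]) + rng.uniform(-1.5, 1.5, size=2)
    radius = rng.uniform(0.42, 0.46) * s

    yy, xx = np.mgrid[0:s, 0:s]
    dist = np.hypot(xx + 0.5 - center[0], yy + 0.5 - center[1])
    inside = dist <= radius

    base = np.array([205.0, 125.0, 70.0]) + rng.uniform(-10, 10, size=3)
    shade = 1.0 - 0.22 * (dist / radius) ** 2
    img = np.zeros((s, s, 3), dtype=np.float64)
    img[inside] = base * shade[inside, None]
    img += rng.normal(0.0, 3.0, size=img.shape)  # sensor-like texture

    jitter = rng.uniform(-cfg.brightness_jitter, cfg.brightness_jitter)
    img[inside] += jitter

    quad_mask = None
    if reflex_quadrant is not None:
        if reflex_quadrant not in _QUADRANT_ANGLES:
            raise ValueError("quadrant must be in {0, 1, 2, 3}")
        qm = np.zeros((s, s))
        half = s // 2
        ys = slice(0, half) if reflex_quadrant in (0, 1) else slice(half, s)
        xs = slice(0, half) if reflex_quadrant in (0, 2) else slice(half, s)
        qm[ys, xs] = 1.0
        quad_mask = qm

    n_v = int(rng.integers(cfg.n_vessels[0], cfg.n_vessels[1] + 1))
    n_reflex = max(1, (2 * n_v) // 3)
    arterial = np.zeros(n_v, dtype=bool)
    arterial[rng.choice(n_v, size=n_reflex, replace=False)] = True

    centerlines, widths = [], []
    theta_range = _QUADRANT_ANGLES.get(reflex_quadrant) \
        if reflex_quadrant is not None else None
    for i in range(n_v):
        tr = theta_range if (theta_range is not None and arterial[i]) else None
        pts = _vessel_geometry(rng, center, radius, theta_range=tr)
        w = rng.uniform(*cfg.vessel_width)
        centerlines.append(pts)
        widths.append(w)
        _stamp(img, pts, w, _VESSEL_COLOR, mode="blend")

    stripe_width = None
    if cls == 1:
        # metallic sheen: clearly above the disc tone in every channel
        # (the disc's green channel stays below ~155), not merely above
        # the dark vessel the stripe sits on
        rb = cfg.reflex_brightness
        stripe_color = np.array([165.0, 110.0, 60.0]) + \
            rb * np.array([1.0, 1.0, 1.0])
        for i in range(n_v):
            if not arterial[i]:
                continue
            stripe_width = cfg.reflex_width_fraction * widths[i]
            _stamp(img, centerlines[i], stripe_width, stripe_color,
                   mode="blend", quad_mask=quad_mask)

    img[~inside] = 0.0
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    rows = np.flatnonzero(inside.any(axis=1))
    cols = np.flatnonzero(inside.any(axis=0))
    geometry = {
        "center": center,
        "radius": radius,
        "bbox": (int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])),
        "centerlines": centerlines,
        "widths": widths,
        "arterial": arterial,
        "reflex_quadrant": reflex_quadrant,
    }
    return FundusSample(image=img, label=cls, seed=sample_seed), geometry


def generate_sample(cls: int, cfg: SynthConfig, sample_seed: int
                    ) -> FundusSample:
    sample, _ = generate_sample_with_geometry(cls, cfg, sample_seed)
    return sample


def centerline_mean_intensity(img: np.ndarray, centerlines: list[np.ndarray]
                              ) -> float:
    """Mean channel-mean intensity sampled along the given centerlines."""
    vals = []
    for pts in centerlines:
        xi = np.clip(np.rint(pts[:, 0]).astype(int), 0, img.shape[1] - 1)
        yi = np.clip(np.rint(pts[:, 1]).astype(int), 0, img.shape[0] - 1)
        vals.append(img[yi, xi].mean())
    return float(np.mean(vals))


def generate_arrays(cfg: SynthConfig) -> tuple[list[np.ndarray], np.ndarray]:
    """In-memory dataset: images and labels, class-alternating sample seeds."""
    images, labels = [], []
    for c in (0, 1):
        for i in range(cfg.n_per_class):
            sample = generate_sample(c, cfg, c * cfg.n_per_class + i)
            images.append(sample.image)
            labels.append(c)
    return images, np.array(labels)


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write n_per_class PNGs per class plus a path,label,seed manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in (0, 1):
        for i in range(cfg.n_per_class):
            sample_seed = c * cfg.n_per_class + i
            sample = generate_sample(c, cfg, sample_seed)
            path = out_dir / f"class{c}_{i:04d}.png"
            save_image(sample.image, path)
            rows.append({"path": str(path), "label": c, "seed": sample_seed})
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
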