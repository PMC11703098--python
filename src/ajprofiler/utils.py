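"""Small shared helpers: label-map boundaries, disc kernels, seeding."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

#: 8-connectivity shifts (row, col)
SHIFTS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Pixels whose 8-neighborhood contains >=2 distinct nonzero labels.

    This is the border definition used throughout: a pixel is a border pixel
    iff at least two different cells meet in its 3x3 neighborhood.  The image
    frame itself is never a border (out-of-frame neighbors are ignored).
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    lo = np.full((h, w), np.iinfo(np.int64).max, dtype=np.int64)
    hi = np.zeros((h, w), dtype=np.int64)
    views = [labels]
    for dr, dc in SHIFTS_8:
        shifted = np.full_like(labels, 0)
        rs = slice(max(dr, 0), h + min(dr, 0))
        cs = slice(max(dc, 0), w + min(dc, 0))
        rs_src = slice(max(-dr, 0), h + min(-dr, 0))
        cs_src = slice(max(-dc, 0), w + min(-dc, 0))
        shifted[rs, cs] = labels[rs_src, cs_src]
        views.append(shifted)
    for v in views:
        nz = v > 0
        lo[nz] = np.minimum(lo[nz], v[nz])
        hi[nz] = np.maximum(hi[nz], v[nz])
    return (hi > 0) & (lo < hi)


def neighbor_label_pairs(labels: np.ndarray, coords: np.ndarray) -> list[tuple[int, ...]]:
    """Sorted tuple of distinct nonzero labels in the 3x3 neighborhood of each coord."""
    labels = np.asarray(labels)
    h, w = labels.shape
    out = []
    for r, c in coords:
        r0, r1 = max(r - 1, 0), min(r + 2, h)
        c0, c1 = max(c - 1, 0), min(c + 2, w)
        vals = np.unique(labels[r0:r1, c0:c1])
        out.append(tuple(int(v) for v in vals if v > 0))
    return out


def disc_kernel(radius: int) -> np.ndarray:
    """Boolean disc structuring element (diameter 2*radius+1 including center)."""
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return (x * x + y * y) <= radius * radius


def gaussian_disc_kernel(radius: int, sigma: float | None = None) -> np.ndarray:
    """Gaussian weights restricted to a disc support, normalized to sum 1."""
    if sigma is None:
        sigma = max(radius / 1.5, 0.5)
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    k = np.exp(-(x * x + y * y) / (2.0 * sigma * sigma))
    k[~disc_kernel(radius)] = 0.0
    return k / k.sum()


def smooth_disc(image: np.ndarray, radius: int = 2) -> np.ndarray:
    """Convolve with a disc-supported Gaussian kernel."""
    return ndimage.convolve(np.asarray(image, dtype=np.float64), gaussian_disc_kernel(radius), mode="nearest")


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Derive a per-stage sub-seed by a fixed counter scheme (stays < 2**31)."""
    return (int(global_seed) * 100_003 + 7919 * int(stage_index) + 1) % (2**31 - 1)
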