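"""Nucleus, cell and cell-border segmentation.

Nuclei are found in the nuclear channel by disc-kernel Gaussian smoothing,
Otsu binarization, opening/closing and a distance-transform watershed to
split touching nuclei.  Cells are then recovered from the junction channel by
a seeded watershed on an edge-strength image, using the nuclei as seeds: one
basin per nucleus, with ridge pixels between basins as the cell borders.

Conventions: coordinates are 0-based (row, col); label maps are row-major
integer grids with background 0; the set of cell labels equals the set of
nucleus labels.  A border pixel is a pixel whose 8-neighborhood contains at
least two distinct cell labels; the image frame is never a border.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.morphology import binary_closing, binary_opening
from skimage.segmentation import watershed

from .utils import boundary_mask, disc_kernel, smooth_disc

DISC_DIAMETER = 5  # px; implemented as radius-2 disc (diameter 5 incl. center)
MIN_NUCLEUS_AREA = 80  # px^2 at the reference resolution


@dataclass
class SegmentationResult:
    """Per-site segmentation: nucleus labels, cell labels, border mask."""

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    border_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(len(np.unique(self.cell_labels[self.cell_labels > 0])))


def normalize_quantile(image: np.ndarray, q_low: float = 0.01, q_high: float = 0.99) -> np.ndarray:
    """Clip to the [q_low, q_high] intensity quantiles and map to [0, 1].

    Degenerate images (both quantiles equal) map to all zeros with a warning.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    lo, hi = np.quantile(image, [q_low, q_high])
    if hi <= lo:
        warnings.warn("degenerate intensity range; returning all-zero image", stacklevel=2)
        return np.zeros_like(image)
    return (np.clip(image, lo, hi) - lo) / (hi - lo)


def segment_nuclei(
    nuclei_image: np.ndarray,
    min_area: int = MIN_NUCLEUS_AREA,
    peak_min_distance: int = 10,
    disc_radius: int = DISC_DIAMETER // 2,
    min_contrast: float = 0.25,
) -> np.ndarray:
    """Label nuclei in a normalized ([0,1]) nuclear-channel image.

    Pipeline: Gaussian smoothing on a disc support (5 px diameter), Otsu
    binarization, morphological opening then closing (disc element), then a
    distance-transform watershed to split touching nuclei.  Components below
    ``min_area`` px^2 are dropped.  An image with nothing above the Otsu
    threshold yields an empty labeling (all zeros), not an error.
    """
    img = smooth_disc(np.asarray(nuclei_image, dtype=np.float64), disc_radius)
    if img.max() <= img.min():
        return np.zeros(img.shape, dtype=np.int32)
    binary = img > threshold_otsu(img)
    # Otsu always splits the histogram, even for structure-free noise; demand
    # a minimum foreground/background separation before accepting any nuclei
    if binary.any() and not binary.all():
        if img[binary].mean() - img[~binary].mean() < min_contrast:
            return np.zeros(img.shape, dtype=np.int32)
    selem = disc_kernel(disc_radius)
    binary = binary_closing(binary_opening(binary, selem), selem)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)

    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(dist, min_distance=peak_min_distance, labels=binary, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndimage.label(binary)
    else:
        labels = watershed(-dist, markers=markers, mask=binary)

    # area filter + sequential relabel
    out = np.zeros(img.shape, dtype=np.int32)
    nxt = 1
    for lab in np.unique(labels[labels > 0]):
        m = labels == lab
        if m.sum() >= min_area:
            out[m] = nxt
            nxt += 1
    return out


def _edge_strength(junction_smoothed: np.ndarray, method: str = "morph") -> np.ndarray:
    if method == "morph":
        selem = disc_kernel(1)
        return ndimage.grey_dilation(junction_smoothed, footprint=selem) - ndimage.grey_erosion(
            junction_smoothed, footprint=selem
        )
    if method == "sobel":
        gr = ndimage.sobel(junction_smoothed, axis=0)
        gc = ndimage.sobel(junction_smoothed, axis=1)
        return np.hypot(gr, gc)
    raise ValueError(f"unknown gradient method {method!r}")


def segment_cells(
    junction_image: np.ndarray,
    nucleus_labels: np.ndarray,
    gradient: str = "morph",
    disc_radius: int = DISC_DIAMETER // 2,
    provenance: dict | None = None,
) -> SegmentationResult:
    """Seeded-watershed cell segmentation from a normalized junction image.

    The image is median-filtered on a disc (5 px diameter), an edge-strength
    image is computed (morphological gradient by default, Sobel magnitude as
    an alternative) and a watershed is flooded from the nucleus labels.  Each
    basin is one cell (same label as its nucleus); border pixels are those
    whose 8-neighborhood spans >= 2 basins.
    """
    nucleus_labels = np.asarray(nucleus_labels)
    if junction_image.shape != nucleus_labels.shape:
        raise ValueError("junction image and nucleus labels must share a shape")
    if nucleus_labels.max() == 0:
        raise ValueError("no nuclei to seed the watershed with")
    img = np.asarray(junction_image, dtype=np.float64)
    smoothed = median_filter(img, footprint=disc_kernel(disc_radius))
    grad = _edge_strength(smoothed, gradient)
    cells = watershed(grad, markers=nucleus_labels.astype(np.int32))
    border = boundary_mask(cells)
    return SegmentationResult(
        nucleus_labels=nucleus_labels.astype(np.int32),
        cell_labels=cells.astype(np.int32),
        border_mask=border,
        provenance=provenance or {},
    )


def border_pixels(result: SegmentationResult, margin: int = 0) -> np.ndarray:
    """Border-mask coordinates >= ``margin`` px from every image edge.

    Returned in deterministic row-major order as an (n, 2) int array.
    """
    mask = result.border_mask
    h, w = mask.shape
    if margin > 0:
        keep = np.zeros_like(mask)
        if h > 2 * margin and w > 2 * margin:
            keep[margin : h - margin, margin : w - margin] = True
        mask = mask & keep
    return np.argwhere(mask)
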