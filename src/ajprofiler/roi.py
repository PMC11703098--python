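"""Border-centered ROI sampling and training-time augmentation.

A ROI is a square patch of the junction channel (default 64x64 px) whose
center pixel lies on a cell border.  Patches are stored already normalized to
[0, 1] so that augmentation, training and inference all share one intensity
scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

DEFAULT_ROI_SIZE = 64
DEFAULT_MIN_SPACING = 8

#: morphology class code book (0 is reserved for background in class maps)
CLASS_NAMES = {
    1: "linear",
    2: "reticular",
    3: "foci",
    4: "disturbed",
    5: "highly_disturbed",
}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}


@dataclass
class ROISet:
    """Ordered collection of fixed-size junction patches with metadata.

    ``patches`` has shape (n, S, S), float32 in [0, 1].  ``meta`` is aligned
    row-wise and carries at least columns row, col, plate, well, site,
    condition; labeled training sets also carry ``morph_class`` (1..5).
    """

    patches: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float32)
        if self.patches.ndim == 2:  # allow a single patch
            self.patches = self.patches[None]
        n = len(self.patches)
        if self.meta is None or len(self.meta) == 0:
            self.meta = pd.DataFrame(index=range(n))
        if len(self.meta) != n:
            raise ValueError("meta rows must align with patches")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def size(self) -> int:
        return self.patches.shape[1] if len(self) else 0

    @property
    def labels(self) -> np.ndarray | None:
        if "morph_class" in self.meta.columns:
            return self.meta["morph_class"].to_numpy(dtype=np.int64)
        return None

    def subset(self, idx) -> "ROISet":
        idx = np.asarray(idx)
        return ROISet(self.patches[idx], self.meta.iloc[idx].reset_index(drop=True))

    @classmethod
    def concat(cls, sets: list["ROISet"]) -> "ROISet":
        sets = [s for s in sets if len(s)]
        if not sets:
            return cls(np.zeros((0, DEFAULT_ROI_SIZE, DEFAULT_ROI_SIZE), np.float32))
        return cls(
            np.concatenate([s.patches for s in sets]),
            pd.concat([s.meta for s in sets], ignore_index=True),
        )

    def save(self, prefix: str) -> None:
        """Persist as multi-page TIFF (patches) + CSV sidecar (metadata)."""
        tifffile.imwrite(f"{prefix}.tif", self.patches)
        self.meta.to_csv(f"{prefix}.csv", index=False)
        with open(f"{prefix}.classes.json", "w") as fh:
            json.dump({str(k): v for k, v in CLASS_NAMES.items()}, fh, indent=1)

    @classmethod
    def load(cls, prefix: str) -> "ROISet":
        patches = tifffile.imread(f"{prefix}.tif")
        meta = pd.read_csv(f"{prefix}.csv")
        return cls(patches, meta)


def eligible_centers(border_coords: np.ndarray, shape: tuple[int, int], size: int) -> np.ndarray:
    """Border coordinates whose size x size footprint fits inside the image."""
    if len(border_coords) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    coords = np.asarray(border_coords, dtype=np.int64)
    half = size // 2
    h, w = shape
    ok = (
        (coords[:, 0] >= half)
        & (coords[:, 0] + half <= h)
        & (coords[:, 1] >= half)
        & (coords[:, 1] + half <= w)
    )
    return coords[ok]


def _greedy_spaced_subset(coords: np.ndarray, n: int, min_spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Random order greedy selection honoring a pairwise minimum spacing.

    Uses a spatial hash with bucket side ``min_spacing`` so each candidate is
    only compared against accepted points in its 3x3 bucket neighborhood.
    """
    order = rng.permutation(len(coords))
    if min_spacing <= 0:
        return coords[order[:n]]
    cell = float(min_spacing)
    buckets: dict[tuple[int, int], list[np.ndarray]] = {}
    chosen = []
    min_sq = min_spacing * min_spacing
    for i in order:
        p = coords[i]
        b = (int(p[0] // cell), int(p[1] // cell))
        ok = True
        for db in range(-1, 2):
            for dc in range(-1, 2):
                for q in buckets.get((b[0] + db, b[1] + dc), ()):
                    d = p - q
                    if d[0] * d[0] + d[1] * d[1] < min_sq:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            chosen.append(p)
            buckets.setdefault(b, []).append(p)
            if len(chosen) == n:
                break
    return np.array(chosen, dtype=np.int64).reshape(-1, 2)


def sample_rois(
    image: np.ndarray,
    border_coords: np.ndarray,
    n: int,
    size: int = DEFAULT_ROI_SIZE,
    min_spacing: float = DEFAULT_MIN_SPACING,
    seed: int = 0,
    meta: dict | None = None,
) -> ROISet:
    """Sample ``n`` square patches centered on border pixels.

    The image must already be normalized (values in [0, 1]) and illumination
    corrected.  Centers are drawn uniformly without replacement from
    ``border_coords``, rejecting candidates closer than ``min_spacing`` px to
    an accepted center.  Deterministic given ``seed``.  If fewer than ``n``
    eligible centers exist, all of them are returned with a warning.
    """
    if size % 2:
        raise ValueError("ROI size must be even")
    image = np.asarray(image)
    if n > 0 and (border_coords is None or len(border_coords) == 0):
        raise ValueError("no border coordinates to sample from")
    if n == 0:
        return ROISet(np.zeros((0, size, size), np.float32))
    coords = eligible_centers(border_coords, image.shape, size)
    if len(coords) == 0:
        raise ValueError("no border coordinates far enough from the image edge")
    rng = np.random.default_rng(seed)
    centers = _greedy_spaced_subset(coords, n, min_spacing, rng)
    if len(centers) < n:
        warnings.warn(
            f"requested {n} ROIs but only {len(centers)} eligible centers "
            f"under min_spacing={min_spacing}", stacklevel=2,
        )
    half = size // 2
    patches = np.stack([image[r - half : r + half, c - half : c + half] for r, c in centers])
    df = pd.DataFrame({"row": centers[:, 0], "col": centers[:, 1]})
    for k, v in (meta or {}).items():
        df[k] = v
    return ROISet(patches.astype(np.float32), df)


def per_image_quota(n_total: int, n_images: int) -> list[int]:
    """Even per-image quotas for a dataset-level request: ceil division with
    truncation on the last images so quotas sum exactly to ``n_total``."""
    if n_images <= 0:
        raise ValueError("need at least one image")
    q = -(-n_total // n_images)  # ceil
    quotas = []
    left = n_total
    for _ in range(n_images):
        take = min(q, left)
        quotas.append(take)
        left -= take
    return quotas


def augment(patch: np.ndarray, rng: np.random.Generator,
            brightness: float = 0.1, contrast: tuple[float, float] = (0.8, 1.25)) -> np.ndarray:
    """Mirror/brightness/contrast augmentation of a [0, 1] patch.

    Independent coin flips for horizontal and vertical mirroring, a brightness
    shift ~ U(-brightness, +brightness) and a contrast scale ~ U(*contrast*)
    applied about the patch mean, clipped back to [0, 1].
    """
    p = np.asarray(patch, dtype=np.float32)
    if rng.random() < 0.5:
        p = p[:, ::-1]
    if rng.random() < 0.5:
        p = p[::-1, :]
    delta = rng.uniform(-brightness, brightness)
    gamma = rng.uniform(*contrast)
    m = p.mean()
    p = (p - m) * gamma + m + delta
    return np.clip(p, 0.0, 1.0)


def augment_batch(batch: np.ndarray, rng: np.random.Generator,
                  brightness: float = 0.1, contrast: tuple[float, float] = (0.8, 1.25)) -> np.ndarray:
    """Vectorized ``augment`` over a (n, S, S) batch (one draw set per patch)."""
    out = np.array(batch, dtype=np.float32, copy=True)
    n = len(out)
    hflip = rng.random(n) < 0.5
    vflip = rng.random(n) < 0.5
    delta = rng.uniform(-brightness, brightness, n).astype(np.float32)
    gamma = rng.uniform(contrast[0], contrast[1], n).astype(np.float32)
    out[hflip] = out[hflip, :, ::-1]
    out[vflip] = out[vflip, ::-1, :]
    m = out.mean(axis=(1, 2), keepdims=True)
    out = (out - m) * gamma[:, None, None] + m + delta[:, None, None]
    return np.clip(out, 0.0, 1.0)
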