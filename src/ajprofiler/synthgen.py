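"""Synthetic two-channel endothelial-monolayer images with full ground truth.

The generator emulates a confluent "cobblestone" monolayer as imaged in a
nuclear stain + junction stain pair: cells form a Voronoi tessellation of
jittered grid seeds, nuclei are bright elliptical blobs at the seeds, and the
junction signal is rendered along the tessellation edges in one of five
border-morphology classes (linear, reticular, foci, disturbed, highly
disturbed).  Multiplicative vignetting, occasional bright debris and camera
noise complete the forward model.  Every intermediate (cell label map, border
class map, vignette field) is returned as ground truth so the whole
downstream pipeline — segmentation, ROI sampling, CNN training, clustering —
is testable without real data.

Morphology is assigned per border segment (the edge between two cells), not
per cell: the unit of phenotype is the border.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import LineString, box

from . import roi as roi_mod
from .roi import CLASS_NAMES, ROISet
from .segmentation import normalize_quantile
from .utils import boundary_mask, neighbor_label_pairs

INTENSITY_MAX = 65535.0
MIN_CELL_AREA = 400.0  # px^2: reject configs whose mean cell area is below this


def uniform_mix() -> dict[int, float]:
    return {c: 1.0 / 5.0 for c in CLASS_NAMES}


@dataclass
class RenderParams:
    """Geometry and intensity of the five border renderers (16-bit units).

    The source imagery gives no quantitative geometry for the classes; these
    defaults were chosen once for visual plausibility and are config-exposed.
    """

    # linear: smooth thin bright line
    linear_amp: float = 22000.0
    linear_sigma: float = 1.0
    # reticular: widened mesh/honeycomb band of small rings
    reticular_amp: float = 14000.0
    reticular_ring_radius: float = 3.2
    reticular_ring_spacing: float = 4.5
    reticular_sigma: float = 0.8
    # foci: short bright perpendicular zig-zag fingers
    foci_amp: float = 18000.0
    foci_finger_len: float = 5.0
    foci_finger_spacing: float = 3.5
    foci_sigma: float = 0.8
    # disturbed: fragmented line with gaps
    disturbed_amp: float = 16000.0
    disturbed_gap_fraction: float = 0.45
    disturbed_chunk_len: float = 6.0
    disturbed_sigma: float = 0.9
    # highly disturbed: wide dim diffuse band
    hd_amp: float = 5200.0
    hd_sigma: float = 3.0


@dataclass
class SynthConfig:
    """Forward-model parameters for one synthetic site."""

    image_size: tuple[int, int] = (512, 512)
    n_cells: int = 25
    morphology_mix: dict[int, float] = field(default_factory=uniform_mix)
    noise: tuple[float, float] = (150.0, 0.0)  # (gaussian_sd, poisson_scale), 16-bit units
    vignette_strength: float = 0.25  # relative corner falloff in [0, 1)
    debris_rate: float = 0.3  # expected bright debris blobs per image
    seed: int = 0
    render: RenderParams = field(default_factory=RenderParams)

    def validate(self) -> None:
        h, w = self.image_size
        if h < 128 or w < 128:
            raise ValueError("image_size must be at least 128x128")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (0.0 <= self.vignette_strength < 1.0):
            raise ValueError("vignette_strength must lie in [0, 1)")
        mix = self.morphology_mix
        if any(p < 0 for p in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("morphology_mix must be nonnegative and sum to 1")
        if any(c not in CLASS_NAMES for c in mix):
            raise ValueError("morphology_mix keys must be class codes 1..5")
        if h * w / self.n_cells < MIN_CELL_AREA:
            raise ValueError(
                f"n_cells={self.n_cells} too large for {h}x{w}: mean cell area "
                f"falls below {MIN_CELL_AREA:.0f} px^2"
            )

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class MonolayerTruth:
    """Everything the generator knows about one synthetic site."""

    nucleus_centers: np.ndarray  # (n, 2) float (row, col)
    cell_label_map: np.ndarray  # int, 0 = none
    border_class_map: np.ndarray  # int, 0 = background, 1..5 = morphology class
    vignette_field: np.ndarray  # positive float
    morphology_mix: dict[int, float]
    edge_classes: dict[tuple[int, int], int] = field(default_factory=dict)
    edge_polylines: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def true_edge_mask(self) -> np.ndarray:
        """Boolean mask of the tessellation edges (label-map boundary pixels)."""
        return boundary_mask(self.cell_label_map)


# ---------------------------------------------------------------------------
# geometry

def _seed_points(n_cells: int, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid seeds: cobblestone-like geometry with controllable count."""
    h, w = shape
    k1 = max(int(np.floor(np.sqrt(n_cells * h / w))), 1)
    k2 = int(np.ceil(n_cells / k1))
    rows = (np.arange(k1) + 0.5) * h / k1
    cols = (np.arange(k2) + 0.5) * w / k2
    pts = np.array([(r, c) for r in rows for c in cols])
    jitter_r = 0.3 * h / k1
    jitter_c = 0.3 * w / k2
    pts = pts + rng.uniform(-1, 1, pts.shape) * [jitter_r, jitter_c]
    pts[:, 0] = np.clip(pts[:, 0], 2, h - 3)
    pts[:, 1] = np.clip(pts[:, 1], 2, w - 3)
    keep = rng.permutation(len(pts))[:n_cells]
    return pts[np.sort(keep)]


def _voronoi_edges(points: np.ndarray, shape: tuple[int, int]) -> dict[tuple[int, int], np.ndarray]:
    """Finite Voronoi ridge segments between cells, clipped to the image box.

    Mirrors the seed set across all four image edges so every ridge between
    two true seeds is finite, then clips each ridge segment to the frame.
    Keys are 1-based (label_a, label_b) pairs with a < b; values are (k, 2)
    arrays of (row, col) polyline vertices.
    """
    n = len(points)
    if n < 2:
        return {}
    h, w = shape
    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, float(h)), (1, 0.0), (1, float(w))):
        m = points.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    allpts = np.vstack(mirrored)
    vor = Voronoi(allpts[:, ::-1])  # Voronoi in (x, y) = (col, row)
    frame = box(0, 0, w - 1, h - 1)
    edges: dict[tuple[int, int], np.ndarray] = {}
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n or q >= n or -1 in verts:
            continue
        seg = LineString(vor.vertices[verts])
        clipped = seg.intersection(frame)
        if clipped.is_empty or clipped.length < 1e-9:
            continue
        xy = np.asarray(clipped.coords)
        a, b = sorted((p + 1, q + 1))
        edges[(a, b)] = xy[:, ::-1]  # back to (row, col)
    return edges


def _densify(polyline: np.ndarray, step: float = 0.5) -> np.ndarray:
    """Resample a polyline at roughly ``step``-px arclength spacing."""
    pts = [polyline[0]]
    for a, b in zip(polyline[:-1], polyline[1:]):
        d = float(np.hypot(*(b - a)))
        k = max(int(np.ceil(d / step)), 1)
        for t in np.linspace(0, 1, k + 1)[1:]:
            pts.append(a + t * (b - a))
    return np.asarray(pts)


# ---------------------------------------------------------------------------
# rendering

def _splat(canvas: np.ndarray, points: np.ndarray, amps: np.ndarray, sigma: float) -> None:
    """Accumulate sub-pixel Gaussian splats onto the canvas in place."""
    h, w = canvas.shape
    rad = int(np.ceil(3 * sigma))
    for (r, c), a in zip(points, amps):
        r0, r1 = int(np.floor(r)) - rad, int(np.floor(r)) + rad + 1
        c0, c1 = int(np.floor(c)) - rad, int(np.floor(c)) + rad + 1
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1, cc1 = min(r1, h), min(c1, w)
        if rr0 >= rr1 or cc0 >= cc1:
            continue
        ys = np.arange(rr0, rr1) - r
        xs = np.arange(cc0, cc1) - c
        k = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma * sigma))
        canvas[rr0:rr1, cc0:cc1] += a * k


def render_border_segment(
    class_code: int,
    polyline: np.ndarray,
    canvas: np.ndarray,
    params: RenderParams | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one border segment in its morphology class onto ``canvas``.

    linear: smooth thin bright line; reticular: widened honeycomb band of
    small rings; foci: short bright perpendicular zig-zag fingers; disturbed:
    fragmented line with gaps; highly disturbed: wide dim diffuse band.
    Returns the canvas (modified in place).
    """
    if class_code not in CLASS_NAMES:
        raise ValueError(f"unknown morphology class code {class_code}")
    params = params or RenderParams()
    rng = rng or np.random.default_rng(0)
    polyline = np.asarray(polyline, dtype=np.float64)
    if polyline.ndim != 2 or len(polyline) < 2:
        return canvas
    pts = _densify(polyline, step=0.5)
    n = len(pts)
    # unit tangents/normals per sample
    tang = np.gradient(pts, axis=0)
    norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    norm /= np.maximum(np.linalg.norm(norm, axis=1, keepdims=True), 1e-9)
    arclen = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])

    name = CLASS_NAMES[class_code]
    if name == "disturbed" and params.disturbed_gap_fraction >= 1.0:
        return canvas  # fully gapped segment draws nothing at all
    # every class keeps a faint continuous spine along the interface: even
    # disrupted junctions retain residual cadherin signal at the cell-cell
    # contact, and it anchors the border to the tessellation edge
    if name != "linear":
        _splat(canvas, pts, 0.35 * params.linear_amp * np.ones(n) * 0.5, params.linear_sigma)
    if name == "linear":
        amps = params.linear_amp * rng.uniform(0.9, 1.1, n)
        _splat(canvas, pts, 0.5 * amps, params.linear_sigma)
    elif name == "reticular":
        # rings marching along the edge form the honeycomb band
        _splat(canvas, pts, 0.25 * params.reticular_amp * np.ones(n), params.reticular_sigma)
        n_rings = max(int(arclen[-1] / params.reticular_ring_spacing), 1)
        for i in range(n_rings):
            s = (i + 0.5) * arclen[-1] / n_rings
            j = int(np.searchsorted(arclen, s))
            j = min(j, n - 1)
            center = pts[j] + norm[j] * rng.uniform(-1.0, 1.0)
            th = np.linspace(0, 2 * np.pi, 20, endpoint=False)
            ring = center + params.reticular_ring_radius * np.stack([np.sin(th), np.cos(th)], axis=1)
            _splat(canvas, ring, 0.35 * params.reticular_amp * np.ones(len(ring)), params.reticular_sigma)
    elif name == "foci":
        _splat(canvas, pts, 0.2 * params.foci_amp * np.ones(n), params.foci_sigma)
        n_fingers = max(int(arclen[-1] / params.foci_finger_spacing), 1)
        side = 1.0
        for i in range(n_fingers):
            s = (i + 0.5) * arclen[-1] / n_fingers
            j = min(int(np.searchsorted(arclen, s)), n - 1)
            length = params.foci_finger_len * rng.uniform(0.7, 1.3)
            ts = np.arange(0.0, length, 0.5)
            finger = pts[j] + side * np.outer(ts - length / 2, norm[j])
            # slight shear gives the zig-zag look
            finger = finger + np.outer(ts, tang[j]) * 0.3
            _splat(canvas, finger, 0.5 * params.foci_amp * np.ones(len(finger)), params.foci_sigma)
            side = -side
    elif name == "disturbed":
        gap = params.disturbed_gap_fraction
        chunk = np.maximum(params.disturbed_chunk_len, 1.0)
        keep = np.ones(n, dtype=bool)
        n_chunks = max(int(np.ceil(arclen[-1] / chunk)), 1)
        drawn = rng.random(n_chunks) >= gap
        idx = np.minimum((arclen / chunk).astype(int), n_chunks - 1)
        keep = drawn[idx]
        amps = params.disturbed_amp * rng.uniform(0.7, 1.2, n)
        jittered = pts + norm * rng.normal(0.0, 0.6, n)[:, None]
        _splat(canvas, jittered[keep], 0.5 * amps[keep], params.disturbed_sigma)
    else:  # highly_disturbed
        amps = params.hd_amp * rng.uniform(0.4, 1.4, n)
        jittered = pts + norm * rng.normal(0.0, 1.0, n)[:, None]
        _splat(canvas, jittered, 0.5 * amps, params.hd_sigma)
    return canvas


def _vignette_field(shape: tuple[int, int], strength: float) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    r2 = (rr - (h - 1) / 2) ** 2 + (cc - (w - 1) / 2) ** 2
    return 1.0 - strength * r2 / r2.max() if strength > 0 else np.ones(shape)


def apply_vignette_and_noise(
    image: np.ndarray,
    vignette_field: np.ndarray,
    noise_params: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Multiply by the vignette field and add camera noise, clipping at 0.

    ``noise_params`` = (gaussian_sd, poisson_scale): additive Gaussian read
    noise plus an optional Poisson-like shot-noise resampling at the given
    photon scale (0 disables it).
    """
    image = np.asarray(image, dtype=np.float64)
    vignette_field = np.asarray(vignette_field, dtype=np.float64)
    if image.shape != vignette_field.shape:
        raise ValueError("image and vignette field shapes differ")
    if np.any(vignette_field <= 0):
        raise ValueError("vignette field must be strictly positive")
    gaussian_sd, poisson_scale = noise_params
    out = image * vignette_field
    if poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) / poisson_scale) * poisson_scale
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, out.shape)
    return np.clip(out, 0.0, None)


def _paint_border_classes(cell_labels: np.ndarray, edge_classes: dict) -> np.ndarray:
    """Class code per tessellation-boundary pixel, from its adjacent cell pair."""
    out = np.zeros(cell_labels.shape, dtype=np.uint8)
    border = boundary_mask(cell_labels)
    coords = np.argwhere(border)
    pairs = neighbor_label_pairs(cell_labels, coords)
    for (r, c), labs in zip(coords, pairs):
        code = 0
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                code = edge_classes.get((labs[i], labs[j]), 0)
                if code:
                    break
            if code:
                break
        out[r, c] = code
    return out


def generate_monolayer(config: SynthConfig) -> tuple[np.ndarray, np.ndarray, MonolayerTruth]:
    """Render one synthetic site: (nuclei_image, junction_image, truth).

    Both images are uint16.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    centers = _seed_points(config.n_cells, config.image_size, rng)

    # cell label map: exact Voronoi rasterization by nearest seed
    if config.n_cells == 1:
        cell_labels = np.ones((h, w), dtype=np.int32)
        edges = {}
    else:
        tree = cKDTree(centers)
        rr, cc = np.mgrid[0:h, 0:w]
        _, idx = tree.query(np.column_stack([rr.ravel(), cc.ravel()]), workers=1)
        cell_labels = (idx.reshape(h, w) + 1).astype(np.int32)
        edges = _voronoi_edges(centers, config.image_size)

    # one morphology class per border segment
    mix_classes = sorted(config.morphology_mix)
    mix_p = np.array([config.morphology_mix[c] for c in mix_classes], dtype=float)
    edge_classes = {
        key: int(rng.choice(mix_classes, p=mix_p)) for key in sorted(edges)
    }
    border_class_map = _paint_border_classes(cell_labels, edge_classes)

    # nuclei channel: elliptical Gaussian blobs at the seeds
    nuclei = np.full((h, w), 300.0)
    for r, c in centers:
        sr = rng.uniform(6.0, 9.0)
        sc = rng.uniform(6.0, 9.0)
        amp = rng.uniform(18000.0, 28000.0)
        rad = int(np.ceil(3 * max(sr, sc)))
        r0, r1 = max(int(r) - rad, 0), min(int(r) + rad + 1, h)
        c0, c1 = max(int(c) - rad, 0), min(int(c) + rad + 1, w)
        ys = (np.arange(r0, r1) - r) / sr
        xs = (np.arange(c0, c1) - c) / sc
        nuclei[r0:r1, c0:c1] += amp * np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / 2.0)

    # junction channel: faint cytoplasm texture + rendered border segments
    junction = np.full((h, w), 600.0)
    from scipy.ndimage import gaussian_filter

    junction += gaussian_filter(rng.normal(0.0, 900.0, (h, w)), 6.0)
    junction = np.clip(junction, 200.0, None)
    for key in sorted(edges):
        render_border_segment(edge_classes[key], edges[key], junction, config.render, rng)

    # debris: occasional bright blobs in the junction channel
    n_debris = rng.poisson(config.debris_rate) if config.debris_rate > 0 else 0
    for _ in range(n_debris):
        dr, dc = rng.uniform(0, h), rng.uniform(0, w)
        sig = rng.uniform(3.0, 8.0)
        amp = 10.0 * junction.mean()
        _splat(junction, np.array([[dr, dc]]), np.array([amp]), sig)

    vignette = _vignette_field(config.image_size, config.vignette_strength)
    nuclei = apply_vignette_and_noise(nuclei, vignette, config.noise, rng)
    junction = apply_vignette_and_noise(junction, vignette, config.noise, rng)

    truth = MonolayerTruth(
        nucleus_centers=centers,
        cell_label_map=cell_labels,
        border_class_map=border_class_map,
        vignette_field=vignette,
        morphology_mix=dict(config.morphology_mix),
        edge_classes=edge_classes,
        edge_polylines=edges,
    )
    to16 = lambda a: np.clip(a, 0, INTENSITY_MAX).astype(np.uint16)
    return to16(nuclei), to16(junction), truth


# ---------------------------------------------------------------------------
# training data

def _class_purity_ok(
    border_class_map: np.ndarray, center: np.ndarray, class_code: int, size: int, purity: float
) -> bool:
    half = size // 2
    r, c = center
    win = border_class_map[r - half : r + half, c - half : c + half]
    nz = win[win > 0]
    return len(nz) > 0 and (nz == class_code).mean() >= purity


def make_training_set(
    n_per_class: int,
    config: SynthConfig | None = None,
    size: int = 64,
    purity: float = 0.9,
    min_spacing: float = 4.0,
    max_images_per_class: int = 8,
) -> ROISet:
    """Balanced labeled ROI set for the 5-class morphology proxy task.

    For each class, single-class monolayers are generated (degenerate
    morphology mix) and border-centered patches are sampled from the
    quantile-normalized junction channel until ``n_per_class`` patches whose
    footprint passes the class-purity threshold are collected.  Raises if a
    class cannot be filled from ``max_images_per_class`` images.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    config = config or SynthConfig()
    sets = []
    for class_code, class_name in sorted(CLASS_NAMES.items()):
        collected: list[ROISet] = []
        n_left = n_per_class
        for img_idx in range(max_images_per_class):
            sub = config.replace(
                morphology_mix={class_code: 1.0},
                seed=config.seed + 1009 * class_code + img_idx,
            )
            _, junction, truth = generate_monolayer(sub)
            norm = normalize_quantile(junction)
            coords = np.argwhere(truth.border_class_map == class_code)
            coords = roi_mod.eligible_centers(coords, norm.shape, size)
            coords = np.array(
                [c for c in coords if _class_purity_ok(truth.border_class_map, c, class_code, size, purity)]
            ).reshape(-1, 2)
            if len(coords) == 0:
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rs = roi_mod.sample_rois(
                    norm, coords, n_left, size=size, min_spacing=min_spacing,
                    seed=sub.seed, meta={"morph_class": class_code, "source_seed": sub.seed},
                )
            collected.append(rs)
            n_left -= len(rs)
            if n_left <= 0:
                break
        if n_left > 0:
            raise ValueError(
                f"insufficient pure border pixels for class {class_name!r}: "
                f"still missing {n_left} of {n_per_class}"
            )
        sets.append(ROISet.concat(collected))
    return ROISet.concat(sets)


# ---------------------------------------------------------------------------
# on-disk dataset

def write_dataset(
    outdir,
    conditions: dict[str, dict[int, float]],
    wells_per_condition: int = 3,
    sites_per_well: int = 2,
    base_config: SynthConfig | None = None,
    plate: str = "P1",
    seed: int = 0,
) -> "pd.DataFrame":
    """Write a plate of synthetic sites and return its manifest.

    ``conditions`` maps condition name -> morphology mix.  Wells are named
    A01, A02, ... in condition order; each site gets a distinct seed derived
    from ``seed``.  The manifest (CSV at outdir/manifest.csv) has one row per
    site with plate/well/site/condition and the two channel paths.
    """
    import os

    base = base_config or SynthConfig()
    rows = []
    widx = 0
    for cond in sorted(conditions):
        mix = conditions[cond]
        for _ in range(wells_per_condition):
            widx += 1
            well = f"A{widx:02d}"
            for s in range(1, sites_per_well + 1):
                cfg = base.replace(morphology_mix=dict(mix), seed=seed + 7057 * widx + s)
                rows.append(write_site(outdir, plate, well, f"s{s}", cond, cfg))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return manifest


def write_site(
    outdir, plate: str, well: str, site: str, condition: str, config: SynthConfig
) -> dict:
    """Render one site and write the TIFF pair + ground-truth sidecars.

    Returns a manifest row dict (paths + metadata).
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    nuclei, junction, truth = generate_monolayer(config)
    stem = f"{plate}_{well}_{site}"
    p_dapi = os.path.join(outdir, f"{stem}_dapi.tif")
    p_vecad = os.path.join(outdir, f"{stem}_vecad.tif")
    tifffile.imwrite(p_dapi, nuclei)
    tifffile.imwrite(p_vecad, junction)
    np.savez_compressed(
        os.path.join(outdir, f"{stem}_truth.npz"),
        cell_label_map=truth.cell_label_map,
        border_class_map=truth.border_class_map,
        vignette_field=truth.vignette_field.astype(np.float32),
        nucleus_centers=truth.nucleus_centers,
    )
    pd.DataFrame(
        {
            "row": truth.nucleus_centers[:, 0],
            "col": truth.nucleus_centers[:, 1],
            "label": np.arange(1, len(truth.nucleus_centers) + 1),
        }
    ).to_csv(os.path.join(outdir, f"{stem}_truth.csv"), index=False)
    return {
        "plate": plate,
        "well": well,
        "site": site,
        "condition": condition,
        "nuclei_path": p_dapi,
        "junction_path": p_vecad,
    }
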