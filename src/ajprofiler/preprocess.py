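"""Image quality control and retrospective illumination correction.

QC computes per-image summary metrics (focus score, total sum, median, SD and
the 0.01/0.25/0.75/0.99 intensity quantiles) that are screened for outliers;
a failed image disqualifies its whole site (both channels).

Illumination/vignetting is corrected retrospectively per plate and channel:
bright structures and debris are iteratively suppressed (pixels more than
``sd_mult`` SD above the local median are replaced by their direct
neighborhood), the cleaned images are combined by a robust median-weighted
average, the aggregate is Gaussian-smoothed into an artificial background,
and the multiplicative correction image is the scalar mean of that background
divided by the background itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

QC_METRIC_NAMES = ("focus_score", "total_sum", "median", "sd", "q01", "q25", "q75", "q99")


@dataclass
class QCMetrics:
    """Per-image quality metrics plus an outlier flag with reason code."""

    focus_score: float
    total_sum: float
    median: float
    sd: float
    q01: float
    q25: float
    q75: float
    q99: float
    outlier_flag: bool = False
    reason: str = ""

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in QC_METRIC_NAMES}


@dataclass
class CorrectionImage:
    """Multiplicative flat-field correction for one plate/channel."""

    field: np.ndarray
    channel: str = ""
    plate: str = ""

    def __post_init__(self):
        f = np.asarray(self.field, dtype=np.float64)
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("correction field must be finite and strictly positive")
        self.field = f


def compute_qc_metrics(image: np.ndarray) -> QCMetrics:
    """Summary metrics of one image.

    The focus score is the variance of the Laplacian normalized by the squared
    mean intensity — a standard, illumination-robust autofocus statistic
    (sharper image => larger score; constant image => 0).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0 or not np.all(np.isfinite(img)):
        raise ValueError("image must be nonempty and finite")
    mean = img.mean()
    lap = ndimage.laplace(img)
    focus = float(lap.var() / (mean * mean)) if mean != 0 else float(lap.var())
    q01, q25, q75, q99 = np.quantile(img, [0.01, 0.25, 0.75, 0.99])
    return QCMetrics(
        focus_score=focus,
        total_sum=float(img.sum()),
        median=float(np.median(img)),
        sd=float(img.std()),
        q01=float(q01),
        q25=float(q25),
        q75=float(q75),
        q99=float(q99),
    )


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = 1.4826 * mad
    if scale == 0:
        z = np.where(values == med, 0.0, np.inf)
        return z
    return (values - med) / scale


def flag_outliers(metrics: list[QCMetrics], thresholds: dict | None) -> list[QCMetrics]:
    """Flag images whose metrics fall outside configured bounds.

    ``thresholds`` maps metric name -> spec dict with any of ``robust_z``
    (two-sided robust-z cutoff across the population), ``min`` and ``max``
    (absolute bounds).  An empty/None config flags nothing.  Returns the same
    QCMetrics objects with ``outlier_flag``/``reason`` filled in.
    """
    if not metrics:
        raise ValueError("need at least one QCMetrics")
    if not thresholds:
        return metrics
    table = {name: np.array([getattr(m, name) for m in metrics]) for name in QC_METRIC_NAMES}
    for name, spec in thresholds.items():
        if name not in table:
            raise KeyError(f"unknown QC metric {name!r}")
        vals = table[name]
        if "robust_z" in spec:
            z = _robust_z(vals)
            for m, zi in zip(metrics, z):
                if abs(zi) > spec["robust_z"]:
                    m.outlier_flag = True
                    m.reason = (m.reason + f" {name}:robust_z").strip()
        if "min" in spec:
            for m, v in zip(metrics, vals):
                if v < spec["min"]:
                    m.outlier_flag = True
                    m.reason = (m.reason + f" {name}:min").strip()
        if "max" in spec:
            for m, v in zip(metrics, vals):
                if v > spec["max"]:
                    m.outlier_flag = True
                    m.reason = (m.reason + f" {name}:max").strip()
    return metrics


def propagate_site_flags(flags: list[bool], site_ids: list) -> list[bool]:
    """A failed image in any channel discards the whole site."""
    bad_sites = {s for f, s in zip(flags, site_ids) if f}
    return [s in bad_sites for s in site_ids]


def _suppress_bright(img: np.ndarray, local_window: int, sd_mult: float, max_iter: int) -> np.ndarray:
    """Iteratively replace pixels > sd_mult*SD above the local median with the
    mean of their direct (8-)neighborhood, until none remain or max_iter."""
    out = np.asarray(img, dtype=np.float64).copy()
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    for _ in range(max_iter):
        local_med = ndimage.median_filter(out, size=local_window, mode="nearest")
        mask = out > local_med + sd_mult * out.std()
        if not mask.any():
            break
        good = ~mask
        num = ndimage.convolve(np.where(good, out, 0.0), kernel, mode="nearest")
        den = ndimage.convolve(good.astype(np.float64), kernel, mode="nearest")
        repl = np.where(den > 0, num / np.maximum(den, 1e-12), local_med)
        out[mask] = repl[mask]
    return out


def _median_weighted_average(stack: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Per-pixel weighted mean with weights inversely proportional to the
    absolute deviation from the per-pixel median (a robust average)."""
    med = np.median(stack, axis=0)
    w = 1.0 / (np.abs(stack - med) + eps * (1.0 + np.abs(med)))
    return (w * stack).sum(axis=0) / w.sum(axis=0)


def estimate_illumination(
    images: list[np.ndarray],
    local_window: int = 33,
    sd_mult: float = 3.0,
    smooth_sigma: float = 64.0,
    max_iter: int = 10,
    aggregate: str = "median_weighted",
    channel: str = "",
    plate: str = "",
) -> CorrectionImage:
    """Estimate a multiplicative flat-field correction from >= 3 images.

    Steps: (1) per image, iteratively replace pixels more than ``sd_mult`` SD
    above the local median (square window ``local_window``) by the mean of
    their direct neighborhood; (2) aggregate the cleaned images by a
    median-weighted average (or plain per-pixel ``"median"``); (3) smooth the
    aggregate with a Gaussian of ``smooth_sigma`` px; (4) the correction is
    the scalar mean of the smoothed background divided by the smoothed
    background.
    """
    if len(images) < 3:
        raise ValueError("need at least 3 images to estimate illumination")
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError("images must share one shape")
    cleaned = np.stack([_suppress_bright(im, local_window, sd_mult, max_iter) for im in images])
    if aggregate == "median_weighted":
        agg = _median_weighted_average(cleaned)
    elif aggregate == "median":
        agg = np.median(cleaned, axis=0)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    background = ndimage.gaussian_filter(agg, smooth_sigma, mode="nearest")
    if np.any(background <= 0):
        raise ValueError("smoothed background reaches zero; cannot form correction")
    field = background.mean() / background
    return CorrectionImage(field=field, channel=channel, plate=plate)


def correct_illumination(image: np.ndarray, correction: CorrectionImage) -> np.ndarray:
    """Multiply an image by the correction field, preserving its dtype."""
    field = correction.field
    if image.shape != field.shape:
        raise ValueError("image and correction field shapes differ")
    out = np.asarray(image, dtype=np.float64) * field
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    else:
        out = out.astype(image.dtype, copy=False)
    return out


def max_project(stack: list[np.ndarray]) -> np.ndarray:
    """Per-pixel maximum over a z-stack."""
    if len(stack) == 0:
        raise ValueError("empty stack")
    shapes = {im.shape for im in stack}
    if len(shapes) != 1:
        raise ValueError("stack images must share one shape")
    out = stack[0]
    for im in stack[1:]:
        out = np.maximum(out, im)
    return out
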