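"""Aggregate segmentation: bandpass → Otsu threshold → morphology.

Aggregates are brighter than the surrounding field, so segmentation
bandpass-filters the image (difference of Gaussians removes low-frequency
illumination background and high-frequency pixel noise), thresholds the
response automatically with Otsu's between-class-variance criterion, and
cleans the binary result morphologically: open to remove small spots, fill
interior holes, drop components below a minimum area, close to smooth
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .core import Image, SegmentationMask


@dataclass
class SegConfig:
    low_sigma_px: float = 2.0
    high_sigma_px: float = 30.0
    min_object_px: int = 64
    se_radius_px: int = 3
    otsu_bins: int = 256
    threshold_on: str = "bandpass"  # or "raw": threshold the input directly

    def validate(self) -> None:
        if not 0 < self.low_sigma_px < self.high_sigma_px:
            raise ValueError("require 0 < low_sigma_px < high_sigma_px")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be non-negative")
        if self.se_radius_px < 1:
            raise ValueError("se_radius_px must be a positive integer")
        if self.otsu_bins < 2:
            raise ValueError("otsu_bins must be >= 2")
        if self.threshold_on not in ("bandpass", "raw"):
            raise ValueError("threshold_on must be 'bandpass' or 'raw'")


def bandpass_filter(img: Image, cfg: SegConfig | None = None) -> Image:
    """Difference of Gaussians: blur(low_sigma) − blur(high_sigma).

    Zero-mean on constant inputs (the DC component cancels); the output is
    a signed response and is deliberately not clipped.
    """
    cfg = cfg or SegConfig()
    cfg.validate()
    low = ndimage.gaussian_filter(img.values, cfg.low_sigma_px, mode="nearest")
    high = ndimage.gaussian_filter(img.values, cfg.high_sigma_px, mode="nearest")
    out = low - high
    lo = float(out.min())
    hi = float(out.max())
    if hi <= lo:
        hi = lo + 1e-12
    return img.with_values(out, intensity_range=(lo, hi))


def otsu_threshold(values: np.ndarray | Image, bins: int = 256) -> float:
    """Threshold maximizing between-class variance over a binned histogram.

    Returns the bin edge between the two classes; ties are broken toward
    the lowest maximizing threshold.  Raises on constant input, whose
    histogram is degenerate.
    """
    if isinstance(values, Image):
        values = values.values
    vals = np.asarray(values, dtype=np.float64).ravel()
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        raise ValueError("Otsu threshold undefined for a constant image")
    counts, edges = np.histogram(vals, bins=bins, range=(vmin, vmax))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(counts)                      # class-0 weight up to bin t
    m0 = np.cumsum(counts * centers)            # class-0 first moment
    w1 = total - w0
    m_total = m0[-1]
    # candidate split after bin t (t = 0..bins-2); guard empty classes
    w0c, w1c = w0[:-1], w1[:-1]
    mu0 = np.divide(m0[:-1], w0c, out=np.zeros(bins - 1), where=w0c > 0)
    mu1 = np.divide(m_total - m0[:-1], w1c, out=np.zeros(bins - 1), where=w1c > 0)
    between = w0c * w1c * (mu0 - mu1) ** 2
    between[(w0c == 0) | (w1c == 0)] = -np.inf
    t = int(np.argmax(between))                 # argmax takes first = lowest
    return float(edges[t + 1])


def refine_mask(mask: SegmentationMask, cfg: SegConfig | None = None) -> SegmentationMask:
    """Morphological cleanup: open → fill holes → remove small → close."""
    cfg = cfg or SegConfig()
    cfg.validate()
    selem = morphology.disk(cfg.se_radius_px)
    out = morphology.opening(mask.values, selem)
    out = ndimage.binary_fill_holes(out)
    if cfg.min_object_px > 0:
        # drop components with area < min_object_px
        out = morphology.remove_small_objects(out, max_size=cfg.min_object_px - 1)
    out = morphology.closing(out, selem)
    return SegmentationMask(out, pixel_size_um=mask.pixel_size_um)


def segment_aggregates(img: Image, cfg: SegConfig | None = None) -> SegmentationMask:
    """Full pipeline: bandpass, min–max normalize, Otsu, refine.

    The bandpassed response is min–max normalized to [0, 1] before
    thresholding, which makes the result invariant to affine intensity
    rescaling of the input.  ``threshold_on='raw'`` thresholds the input
    intensities instead (still min–max normalized).

    The effective threshold is the larger of the Otsu threshold and a
    robust noise floor (median + 3·1.4826·MAD of the response): Otsu always
    splits a histogram, even a structureless one, and without the floor a
    pure-noise image would percolate into a giant spurious foreground
    component instead of yielding an empty mask.
    """
    cfg = cfg or SegConfig()
    cfg.validate()
    if cfg.threshold_on == "bandpass":
        response = bandpass_filter(img, cfg).values
    else:
        response = img.values
    span = np.ptp(response)
    if span == 0:
        return SegmentationMask(
            np.zeros(img.shape, dtype=bool), pixel_size_um=img.pixel_size_um
        )
    unit = (response - response.min()) / span
    thr = otsu_threshold(unit, cfg.otsu_bins)
    med = float(np.median(unit))
    mad = float(np.median(np.abs(unit - med)))
    thr = max(thr, med + 3.0 * 1.4826 * mad)
    raw = SegmentationMask(unit > thr, pixel_size_um=img.pixel_size_um)
    return refine_mask(raw, cfg)
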