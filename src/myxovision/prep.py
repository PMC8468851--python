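"""Preprocessing pipeline: Lanczos rescale, crop, CLAHE, HE, range scaling.

Raw time-lapse frames have inconsistent contrast between frames and more
resolution than needed to resolve aggregates and streams, so the pipeline
(i) scales down and optionally crops each frame, (ii) normalizes contrast
per frame with CLAHE, (iii) optionally applies global histogram
equalization to enhance the dim inter-aggregate streams, and (iv) maps
intensities to the model/metric range.  The canonical working range is
[0, 1]; [−1, 1] appears only at the model and metric boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image as PILImage
from skimage import exposure

from .core import Image


@dataclass
class PrepConfig:
    downscale_factor: float = 0.5
    crop: tuple[int, int, int, int] | None = None  # (row, col, height, width)
    clahe_clip_limit: float = 0.02  # skimage-normalized, in (0, 1]
    clahe_tile_px: int = 64
    he_bins: int = 256
    target_range: tuple[float, float] = (-1.0, 1.0)

    def validate(self) -> None:
        if not 0 < self.downscale_factor <= 1:
            raise ValueError("downscale_factor must lie in (0, 1]")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive")
        if self.clahe_tile_px < 1:
            raise ValueError("clahe_tile_px must be positive")
        if self.he_bins < 2:
            raise ValueError("he_bins must be >= 2")


def rescale_image(img: Image, factor: float) -> Image:
    """Resample with the Lanczos (windowed-sinc, a=3) kernel.

    Output dimensions are ``round(input * factor)``; the pixel size is
    divided by ``factor`` so the physical field size is preserved.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    nl, nw = img.shape
    out_l, out_w = round(nl * factor), round(nw * factor)
    if out_l < 1 or out_w < 1:
        raise ValueError("rescale factor yields an empty image")
    if (out_l, out_w) == (nl, nw) and factor == 1.0:
        return img.with_values(img.values.copy())
    pil = PILImage.fromarray(img.values.astype(np.float32), mode="F")
    resized = pil.resize((out_w, out_l), resample=PILImage.LANCZOS)
    lo, hi = img.intensity_range
    vals = np.clip(np.asarray(resized, dtype=np.float64), lo, hi)
    return img.with_values(vals, pixel_size_um=img.pixel_size_um / factor)


def crop_image(img: Image, crop: tuple[int, int, int, int]) -> Image:
    row, col, height, width = crop
    nl, nw = img.shape
    if not (0 <= row and 0 <= col and row + height <= nl and col + width <= nw
            and height >= 1 and width >= 1):
        raise ValueError("crop window must lie inside the image")
    return img.with_values(img.values[row:row + height, col:col + width].copy())


def clahe_normalize(img: Image, cfg: PrepConfig | None = None) -> Image:
    """Contrast-limited adaptive histogram equalization.

    Tile-wise equalization with a clip limit corrects uneven illumination
    and drifting contrast between frames.  A constant image is returned
    unchanged — there is no contrast to equalize.
    """
    cfg = cfg or PrepConfig()
    cfg.validate()
    vals = img.values
    lo, hi = img.intensity_range
    if np.ptp(vals) == 0:
        return img.with_values(vals.copy(), intensity_range=(0.0, 1.0))
    # normalize to [0,1] over the image's own span so the result is
    # invariant to affine rescaling of the input
    unit = (vals - vals.min()) / np.ptp(vals)
    tile = min(cfg.clahe_tile_px, *unit.shape)
    out = exposure.equalize_adapthist(
        unit, kernel_size=tile, clip_limit=cfg.clahe_clip_limit
    )
    return img.with_values(out, intensity_range=(0.0, 1.0))


def hist_equalize(img: Image, bins: int = 256) -> Image:
    """Global histogram equalization via the empirical CDF on ``bins`` bins.

    The mapping is monotone non-decreasing in input intensity and fills
    [0, 1]; a constant image maps to a single value.  Not invertible —
    which is exactly why the GAN needs the equalized image as its own
    output channel rather than deriving it from the normalized one.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    vals = img.values
    span = np.ptp(vals)
    if span == 0:
        return img.with_values(np.ones_like(vals), intensity_range=(0.0, 1.0))
    unit = (vals - vals.min()) / span
    counts, edges = np.histogram(unit, bins=bins, range=(0.0, 1.0))
    cdf = np.cumsum(counts).astype(np.float64)
    cdf /= cdf[-1]
    idx = np.minimum((unit * bins).astype(np.intp), bins - 1)
    return img.with_values(cdf[idx], intensity_range=(0.0, 1.0))


def scale_to_range(img: Image, target: tuple[float, float]) -> Image:
    """Affine map of the declared intensity range onto ``target``."""
    lo, hi = img.intensity_range
    tlo, thi = target
    if hi <= lo or thi <= tlo:
        raise ValueError("degenerate intensity range")
    vals = (img.values - lo) / (hi - lo) * (thi - tlo) + tlo
    return img.with_values(vals, intensity_range=(float(tlo), float(thi)))


def preprocess(
    img: Image, cfg: PrepConfig | None = None, *, equalize: bool = False
) -> Image:
    """Full pipeline: rescale → crop → CLAHE → (optional HE) → target range."""
    cfg = cfg or PrepConfig()
    cfg.validate()
    out = rescale_image(img, cfg.downscale_factor)
    if cfg.crop is not None:
        out = crop_image(out, cfg.crop)
    out = clahe_normalize(out, cfg)
    if equalize:
        out = hist_equalize(out, cfg.he_bins)
    return scale_to_range(out, cfg.target_range)
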