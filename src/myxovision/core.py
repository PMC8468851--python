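"""Core containers shared across the toolkit.

Every analysis step operates on 2-D grayscale grids carrying physical pixel
size (μm/pixel) and a declared intensity range.  The intensity range matters
because the evaluation metrics assume images scaled to [−1, 1] while the
preprocessing pipeline works canonically in [0, 1]; carrying the range on the
container keeps conversions explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Image:
    """A 2-D grayscale image with physical calibration.

    Parameters
    ----------
    values : np.ndarray
        2-D float array, shape (Nl, Nw) — rows × columns.
    pixel_size_um : float
        Physical side of one pixel in micrometres.
    intensity_range : tuple of float
        Declared (lo, hi) bounds for the pixel values, lo < hi.
    """

    values: np.ndarray
    pixel_size_um: float = 1.0
    intensity_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("Image requires a 2-D grid with Nl, Nw >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValueError("intensity_range must satisfy lo < hi")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def side_um(self) -> tuple[float, float]:
        """Physical (height, width) of the field in μm."""
        nl, nw = self.values.shape
        return nl * self.pixel_size_um, nw * self.pixel_size_um

    def with_values(self, values: np.ndarray, **kwargs) -> "Image":
        """Copy metadata onto a new value grid (shape may change)."""
        out = replace(self, values=np.asarray(values, dtype=np.float64))
        for k, v in kwargs.items():
            setattr(out, k, v)
        return out

    def clipped(self) -> "Image":
        lo, hi = self.intensity_range
        return self.with_values(np.clip(self.values, lo, hi))


@dataclass
class SegmentationMask:
    """Binary foreground (aggregates) / background grid."""

    values: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def foreground_count(self) -> int:
        return int(self.values.sum())


@dataclass
class AggregateRecord:
    """One connected aggregate: identity, centroid, area, pixel support."""

    id: int
    centroid_px: tuple[float, float]  # (row, col)
    centroid_um: tuple[float, float]  # (x, y) = (col, row) * pixel size
    area_px: int
    pixel_set: frozenset = field(repr=False, default_factory=frozenset)


@dataclass
class GroundTruth:
    """Known answers attached to a synthetic scene."""

    mask: SegmentationMask
    aggregates: list
    wavelength_um: float | None = None
    metadata: dict = field(default_factory=dict)
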