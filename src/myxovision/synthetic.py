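"""Synthetic paired phase-contrast / fluorescence scenes with ground truth.

No public *M. xanthus* time-lapse data accompanies the method, so every
downstream module is exercised on generated scenes whose answers are known by
construction:

* **Aggregate scenes** emulate developing fruiting-body fields.  The
  fluorescence-like rendering has bright, near-uniform aggregates, dimmer
  streams joining neighbouring aggregates, and a noisy near-zero background —
  intensity tracks cell density.  The phase-contrast-like rendering of the
  same scene shows each aggregate as a bright halo rim with interior dark
  bands (shade-off), and hides the streams entirely, mimicking the loss of
  the intensity–density correlation in that modality.
* **Ripple scenes** are plane sinusoids of known wavelength and orientation —
  the traveling cell-density waves seen during predation — at full contrast
  in the fluorescence-like channel and at reduced contrast with heavier noise
  in the phase-contrast-like channel.

Determinism contract: identical parameters (including ``seed``) produce
bit-identical images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import AggregateRecord, GroundTruth, Image, SegmentationMask

# Aggregate radial profile: flat core out to CORE_FRACTION*R, cosine falloff
# reaching zero at (2 - CORE_FRACTION)*R; half-maximum sits exactly at R, so
# the ground-truth support (pixels above half of aggregate_intensity) is the
# disk of radius R.
CORE_FRACTION = 0.8
STREAM_WIDTH_PX = 3.0
MIN_EXTRA_SPACING_PX = 4.0
MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass
class AggregateSceneParams:
    field_size_px: int = 256
    pixel_size_um: float = 1.0
    n_aggregates: int = 5
    radius_range_px: tuple[float, float] = (12.0, 24.0)
    stream_intensity: float = 0.35
    aggregate_intensity: float = 0.9
    background_noise_sigma: float = 0.02
    halo_width_px: float = 4.0
    shade_band_period_px: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.field_size_px < 1:
            raise ValueError("field_size_px must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_aggregates < 0:
            raise ValueError("n_aggregates must be non-negative")
        rmin, rmax = self.radius_range_px
        if not (0 < rmin <= rmax):
            raise ValueError("radius_range_px must satisfy 0 < min <= max")
        if not (0 < self.stream_intensity < 1):
            raise ValueError("stream_intensity must lie in (0, 1)")
        if not (0 < self.aggregate_intensity <= 1):
            raise ValueError("aggregate_intensity must lie in (0, 1]")
        if self.background_noise_sigma < 0:
            raise ValueError("background_noise_sigma must be non-negative")
        if self.halo_width_px <= 0 or self.shade_band_period_px <= 0:
            raise ValueError("halo/shade parameters must be positive")


@dataclass
class RippleSceneParams:
    field_size_px: int = 504
    pixel_size_um: float = 1.0
    wavelength_um: float = 46.0
    orientation_rad: float = 0.0
    amplitude: float = 0.8
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.field_size_px < 1:
            raise ValueError("field_size_px must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.wavelength_um < 2 * self.pixel_size_um:
            raise ValueError(
                "wavelength below the Nyquist limit of 2 pixels "
                f"({2 * self.pixel_size_um} um)"
            )
        if not (0 <= self.orientation_rad < np.pi):
            raise ValueError("orientation_rad must lie in [0, pi)")
        if not (0 <= self.amplitude <= 1):
            raise ValueError("amplitude must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def _place_aggregates(
    params: AggregateSceneParams, rng: np.random.Generator
) -> tuple[list[tuple[float, float, float]], list[str]]:
    """Rejection-sample (row, col, radius) triples with minimum spacing.

    Spacing rule: centre distance >= sum of radii + 4 px, which keeps the
    half-maximum supports disjoint so truth components map one-to-one onto
    the aggregate list.
    """
    n = params.field_size_px
    rmin, rmax = params.radius_range_px
    placed: list[tuple[float, float, float]] = []
    notes: list[str] = []
    for _ in range(params.n_aggregates):
        ok = False
        for _attempt in range(MAX_PLACEMENT_ATTEMPTS):
            radius = float(rng.uniform(rmin, rmax))
            margin = radius + 1.0
            if 2 * margin >= n:
                continue
            row = float(rng.uniform(margin, n - margin))
            col = float(rng.uniform(margin, n - margin))
            if all(
                np.hypot(row - r0, col - c0)
                >= radius + rad0 + MIN_EXTRA_SPACING_PX
                for r0, c0, rad0 in placed
            ):
                placed.append((row, col, radius))
                ok = True
                break
        if not ok:
            msg = (
                f"placed {len(placed)} of {params.n_aggregates} aggregates; "
                "field too crowded for the minimum-spacing rule"
            )
            notes.append(msg)
            warnings.warn(msg, stacklevel=3)
            break
    return placed, notes


def _radial_profile(dist: np.ndarray, radius: float) -> np.ndarray:
    """Plateaued profile: 1 inside the core, cosine falloff, 0 outside."""
    core = CORE_FRACTION * radius
    outer = (2.0 - CORE_FRACTION) * radius
    prof = np.zeros_like(dist)
    prof[dist <= core] = 1.0
    band = (dist > core) & (dist < outer)
    prof[band] = 0.5 * (1.0 + np.cos(np.pi * (dist[band] - core) / (outer - core)))
    return prof


def _draw_segment(
    canvas: np.ndarray, p0: tuple[float, float], p1: tuple[float, float],
    width: float, value: float,
) -> None:
    """Paint max(canvas, value) along the thick segment p0-p1 (row, col)."""
    nl, nw = canvas.shape
    rr, cc = np.mgrid[0:nl, 0:nw]
    d = np.array(p1) - np.array(p0)
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        return
    t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    dist = np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))
    sel = dist <= width / 2.0
    canvas[sel] = np.maximum(canvas[sel], value)


def generate_aggregate_scene(
    params: AggregateSceneParams,
) -> tuple[Image, Image, GroundTruth]:
    """Render paired phase-like / fluorescence-like aggregate fields.

    Returns ``(phase_like, fluor_like, truth)``.  ``truth.mask`` is the union
    of the aggregate half-maximum supports; streams are deliberately excluded
    (they are inter-aggregate features, not aggregates).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.field_size_px
    placed, notes = _place_aggregates(params, rng)

    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    fluor = np.zeros((n, n))
    phase = np.full((n, n), 0.5)
    mask = np.zeros((n, n), dtype=bool)

    records: list[AggregateRecord] = []
    # streams first so aggregates paint over their ends
    centers = [(r, c) for r, c, _ in placed]
    for i, (r0, c0, _rad) in enumerate(placed):
        if len(placed) < 2:
            break
        dists = [
            np.hypot(r0 - r1, c0 - c1) if j != i else np.inf
            for j, (r1, c1, _x) in enumerate(placed)
        ]
        j = int(np.argmin(dists))
        _draw_segment(
            fluor, centers[i], centers[j], STREAM_WIDTH_PX,
            params.stream_intensity,
        )

    for idx, (r0, c0, radius) in enumerate(placed):
        dist = np.hypot(rr - r0, cc - c0)
        prof = _radial_profile(dist, radius)
        fluor = np.maximum(fluor, params.aggregate_intensity * prof)
        support = dist <= radius
        mask |= support

        # phase rendering: bright rim straddling the boundary, interior
        # radial dark bands (shade-off), no stream signal at all
        rim = np.abs(dist - radius) <= params.halo_width_px / 2.0
        interior = dist < radius - params.halo_width_px / 2.0
        phase[rim] = 0.9
        bands = 0.5 + 0.2 * np.cos(
            2 * np.pi * dist[interior] / params.shade_band_period_px
        )
        phase[interior] = bands

        ys, xs = np.nonzero(support)
        centroid = (float(ys.mean()), float(xs.mean())) if ys.size else (r0, c0)
        records.append(
            AggregateRecord(
                id=idx,
                centroid_px=centroid,
                centroid_um=(
                    centroid[1] * params.pixel_size_um,
                    centroid[0] * params.pixel_size_um,
                ),
                area_px=int(support.sum()),
                pixel_set=frozenset(zip(ys.tolist(), xs.tolist())),
            )
        )

    if params.background_noise_sigma > 0:
        fluor = fluor + rng.normal(0.0, params.background_noise_sigma, (n, n))
        phase = phase + rng.normal(0.0, params.background_noise_sigma, (n, n))
    fluor = np.clip(fluor, 0.0, 1.0)
    phase = np.clip(phase, 0.0, 1.0)

    truth = GroundTruth(
        mask=SegmentationMask(mask, pixel_size_um=params.pixel_size_um),
        aggregates=records,
        metadata={"warnings": notes, "n_requested": params.n_aggregates},
    )
    px = params.pixel_size_um
    return (
        Image(phase, pixel_size_um=px),
        Image(fluor, pixel_size_um=px),
        truth,
    )


def generate_ripple_scene(
    params: RippleSceneParams,
) -> tuple[Image, Image, GroundTruth]:
    """Render paired phase-like / fluorescence-like plane-wave ripple fields.

    The fluorescence-like channel is
    ``amplitude * (1 + sin(2π (x cosφ + y sinφ) · pixel_size / λ)) / 2``
    plus Gaussian noise; the phase-like channel is the same wave at 30%
    contrast around mid-gray with double the noise.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.field_size_px
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    phi = params.orientation_rad
    # x runs along columns, y along rows
    coord_um = (cc * np.cos(phi) + rr * np.sin(phi)) * params.pixel_size_um
    wave = np.sin(2 * np.pi * coord_um / params.wavelength_um)
    fluor = params.amplitude * (1.0 + wave) / 2.0
    phase = 0.5 + 0.3 * params.amplitude * wave / 2.0
    if params.noise_sigma > 0:
        fluor = fluor + rng.normal(0.0, params.noise_sigma, (n, n))
        phase = phase + rng.normal(0.0, 2.0 * params.noise_sigma, (n, n))
    fluor = np.clip(fluor, 0.0, 1.0)
    phase = np.clip(phase, 0.0, 1.0)

    truth = GroundTruth(
        mask=SegmentationMask(
            np.zeros((n, n), dtype=bool), pixel_size_um=params.pixel_size_um
        ),
        aggregates=[],
        wavelength_um=params.wavelength_um,
    )
    px = params.pixel_size_um
    return (
        Image(phase, pixel_size_um=px),
        Image(fluor, pixel_size_um=px),
        truth,
    )
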