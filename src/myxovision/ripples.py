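"""Ripple-wavelength estimation via a polar-binned 2-D DFT.

Traveling cell-density waves appear as a ring of power in the 2-D Fourier
magnitude spectrum.  For an L×L image the spectrum is re-binned radially:
the amplitude at integer wave-number k is the mean DFT magnitude over all
Fourier pixels whose radius from the DC bin lies in [k, k+1).  A window-3
moving average removes small fluctuations, and the wave-number k1 is the
peak of the smoothed profile above a minimum wave-number kmin — peaks below
kmin correspond to gradual large-scale intensity changes (e.g. k < 6 in a
504 μm field means λ > 84 μm, too long to be rippling).  The wavelength is
λ = L / k1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Image

#: longest biologically plausible ripple wavelength, μm; sets the default
#: low-frequency cutoff kmin = ceil(L / LAMBDA_MAX_UM)
LAMBDA_MAX_UM = 84.0


@dataclass
class SpectrumProfile:
    k: np.ndarray                    # integer wave-numbers 0..k_max
    amplitude: np.ndarray            # mean |DFT| in radius band [k, k+1)
    amplitude_smoothed: np.ndarray   # window-3 moving average


@dataclass
class RippleResult:
    k0: int | None      # global peak over k >= 1 (diagnostic, may be rejected)
    k1: int | None      # selected wave-number (None: no ripple detected)
    lambda_um: float | None
    L_um: float
    kmin: int


def default_kmin(L_um: float, lambda_max_um: float = LAMBDA_MAX_UM) -> int:
    """Low-frequency cutoff from the longest plausible wavelength.

    For a 504 μm field and the 84 μm default this gives kmin = 6.
    """
    return max(1, math.ceil(L_um / lambda_max_um))


def _center_crop_square(vals: np.ndarray) -> np.ndarray:
    nl, nw = vals.shape
    if nl == nw:
        return vals
    warnings.warn("non-square image center-cropped to square for the radial DFT",
                  stacklevel=3)
    side = min(nl, nw)
    r0 = (nl - side) // 2
    c0 = (nw - side) // 2
    return vals[r0:r0 + side, c0:c0 + side]


def radial_spectrum(img: Image | np.ndarray) -> SpectrumProfile:
    """Centered 2-D DFT magnitude, averaged over angles per radius band.

    Every Fourier pixel is assigned the radius sqrt(kx² + ky²) about the DC
    bin; amplitude(k) is the mean magnitude over the exact pixel set with
    radius in [k, k+1), no interpolation.  k_max = floor(min(Nl, Nw)/2).
    """
    vals = img.values if isinstance(img, Image) else np.asarray(img, dtype=float)
    if min(vals.shape) < 8:
        raise ValueError("image must be at least 8x8")
    vals = _center_crop_square(vals)
    n = vals.shape[0]
    spec = np.abs(np.fft.fftshift(np.fft.fft2(vals)))
    center = n // 2  # DC lands here after fftshift
    rr, cc = np.mgrid[0:n, 0:n]
    radius = np.hypot(rr - center, cc - center)
    k_max = n // 2
    k_idx = np.floor(radius).astype(np.intp)
    keep = k_idx <= k_max
    sums = np.bincount(k_idx[keep], weights=spec[keep], minlength=k_max + 1)
    cnts = np.bincount(k_idx[keep], minlength=k_max + 1)
    amplitude = sums / np.maximum(cnts, 1)
    k = np.arange(k_max + 1)
    return SpectrumProfile(
        k=k, amplitude=amplitude, amplitude_smoothed=smooth(amplitude)
    )


def smooth(amplitude: np.ndarray) -> np.ndarray:
    """Centered window-3 moving average; endpoints use the 2 available
    neighbors.  Profiles shorter than 3 are returned unsmoothed."""
    a = np.asarray(amplitude, dtype=float)
    if a.size < 3:
        warnings.warn("profile too short to smooth; returned unchanged",
                      stacklevel=2)
        return a.copy()
    out = a.copy()
    out[1:-1] = (a[:-2] + a[1:-1] + a[2:]) / 3.0
    out[0] = (a[0] + a[1]) / 2.0
    out[-1] = (a[-2] + a[-1]) / 2.0
    return out


def smooth_profile(prof: SpectrumProfile) -> SpectrumProfile:
    return SpectrumProfile(
        k=prof.k, amplitude=prof.amplitude,
        amplitude_smoothed=smooth(prof.amplitude),
    )


def detect_wavelength(
    prof: SpectrumProfile,
    L_um: float,
    kmin: int | None = None,
    *,
    peak: str = "global",
) -> RippleResult:
    """Select the peak wave-number above kmin and convert to wavelength.

    ``peak='global'`` (default) takes the argmax of the smoothed amplitude
    over k >= kmin, ties toward the smaller k; ``peak='first-local'`` takes
    the first local maximum at or above kmin instead.  Smoothing locates the
    peak *region*; the selected wave-number is then pinned to the dominant
    unsmoothed bin within one bin of that region, which resolves the
    half-bin ambiguity the moving average introduces for near-monochromatic
    spectra.  k0, the global peak over k >= 1, is recorded for diagnostics.
    When no power is present above kmin a no-ripple sentinel (k1 = None) is
    returned.
    """
    if kmin is None:
        kmin = default_kmin(L_um)
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    amp = prof.amplitude_smoothed
    if prof.k[-1] < kmin:
        raise ValueError("profile does not cover k >= kmin")

    k0 = int(1 + np.argmax(amp[1:]))
    tail = amp[kmin:]
    if np.all(tail == 0):
        return RippleResult(k0=k0, k1=None, lambda_um=None, L_um=L_um, kmin=kmin)

    if peak == "global":
        k1 = int(kmin + np.argmax(tail))  # argmax returns first ⇒ smaller k
    elif peak == "first-local":
        k1 = None
        for i in range(kmin, len(amp)):
            left = amp[i - 1] if i - 1 >= 0 else -np.inf
            right = amp[i + 1] if i + 1 < len(amp) else -np.inf
            if amp[i] >= left and amp[i] > right:
                k1 = i
                break
        if k1 is None:
            k1 = int(kmin + np.argmax(tail))
    else:
        raise ValueError("peak must be 'global' or 'first-local'")
    # pin to the dominant raw bin within the smoothed peak's neighborhood
    lo = max(kmin, k1 - 1)
    hi = min(len(prof.amplitude) - 1, k1 + 1)
    k1 = int(lo + np.argmax(prof.amplitude[lo:hi + 1]))
    return RippleResult(
        k0=k0, k1=k1, lambda_um=L_um / k1, L_um=L_um, kmin=kmin
    )


def estimate_wavelength(
    img: Image,
    L_um: float | None = None,
    kmin: int | None = None,
    **kwargs,
) -> RippleResult:
    """Convenience wrapper: radial spectrum → smoothing → peak detection."""
    if L_um is None:
        L_um = min(img.shape) * img.pixel_size_um
    return detect_wavelength(radial_spectrum(img), L_um, kmin, **kwargs)


def wavelength_timeseries(
    movie: list[Image],
    L_um: float | None = None,
    kmin: int | None = None,
) -> pd.DataFrame:
    """Per-frame wavelength estimates over a movie.

    Returns a DataFrame with columns frame, k1, lambda_um; frames with no
    detectable ripple carry NaN.  The frame's shape must be constant.
    """
    shapes = {im.shape for im in movie}
    if len(shapes) > 1:
        raise ValueError("all frames must share one shape")
    rows = []
    for i, frame in enumerate(movie):
        res = estimate_wavelength(frame, L_um, kmin)
        rows.append({
            "frame": i,
            "k1": res.k1 if res.k1 is not None else np.nan,
            "lambda_um": res.lambda_um if res.lambda_um is not None else np.nan,
        })
    return pd.DataFrame(rows)
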