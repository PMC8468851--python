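"""MSE / SSIM image similarity and their perturbation-equivalence calibration.

Both metrics assume intensities scaled to [−1, 1].  The MSE of two images r
and s is the mean of squared pixel differences, bounded by [0, 4] on that
range.  The SSIM here is the *global* single statistic

    SSIM(r, s) = (2 μr μs + c1)(2 σrs + c2) /
                 ((μr² + μs² + c1)(σr² + σs² + c2)),

computed from whole-image means, variances, and covariance (not the common
windowed-mean variant, which is available behind a flag for comparison).
With the default constants the formula can go negative for strongly
anti-correlated images even though its maximum of 1 is attained exactly at
identity; we return the formula's value as-is.

Because raw MSE/SSIM numbers are hard to interpret, each can be calibrated
into (i) the smallest whole-pixel spatial shift of the real image against
itself that produces an equally bad metric value, and (ii) the standard
deviation of additive i.i.d. Gaussian noise — as a percentage of the
intensity span — that would produce the same MSE (closed form σ = √MSE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Image


@dataclass
class SSIMParams:
    c1: float = 0.004
    c2: float = 0.0036

    def validate(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("c1 and c2 must be positive")


@dataclass
class MetricReport:
    mse: float
    ssim: float
    equiv_shift_mse_um: float        # math.inf when the search capped out
    equiv_shift_ssim_um: float
    equiv_noise_pct: float

    @property
    def shift_capped(self) -> bool:
        return math.isinf(self.equiv_shift_mse_um) or math.isinf(
            self.equiv_shift_ssim_um
        )


def _values(img: Image | np.ndarray) -> np.ndarray:
    return img.values if isinstance(img, Image) else np.asarray(img, dtype=float)


def mse(r: Image | np.ndarray, s: Image | np.ndarray) -> float:
    """Mean squared pixel difference; in [0, 4] for [−1, 1] images."""
    rv, sv = _values(r), _values(s)
    if rv.shape != sv.shape:
        raise ValueError("images must have the same shape")
    return float(np.mean((rv - sv) ** 2))


def ssim(
    r: Image | np.ndarray, s: Image | np.ndarray, p: SSIMParams | None = None
) -> float:
    """Global structural similarity from whole-image moments."""
    p = p or SSIMParams()
    p.validate()
    rv, sv = _values(r), _values(s)
    if rv.shape != sv.shape:
        raise ValueError("images must have the same shape")
    mu_r, mu_s = rv.mean(), sv.mean()
    var_r, var_s = rv.var(), sv.var()
    cov = ((rv - mu_r) * (sv - mu_s)).mean()
    lum = (2 * mu_r * mu_s + p.c1) / (mu_r**2 + mu_s**2 + p.c1)
    struct = (2 * cov + p.c2) / (var_r + var_s + p.c2)
    return float(lum * struct)


def ssim_windowed(
    r: Image | np.ndarray, s: Image | np.ndarray,
    p: SSIMParams | None = None, window: int = 7,
) -> float:
    """Mean of the global statistic over non-overlapping square tiles.

    Offered only for comparison with the conventional windowed SSIM;
    the global statistic above is the default everywhere.
    """
    p = p or SSIMParams()
    rv, sv = _values(r), _values(s)
    if rv.shape != sv.shape:
        raise ValueError("images must have the same shape")
    nl, nw = rv.shape
    vals = []
    for i in range(0, nl - window + 1, window):
        for j in range(0, nw - window + 1, window):
            vals.append(ssim(rv[i:i + window, j:j + window],
                             sv[i:i + window, j:j + window], p))
    return float(np.mean(vals)) if vals else ssim(rv, sv, p)


def shifted_metric(
    r: Image | np.ndarray, d: int, metric: str = "mse",
    p: SSIMParams | None = None,
) -> float:
    """Metric between r and r shifted by d pixels, averaged over the four
    axis directions, evaluated on the overlapping region only (no
    wraparound, no padding)."""
    rv = _values(r)
    if d < 1:
        raise ValueError("shift must be a positive integer")
    fn = mse if metric == "mse" else (lambda a, b: ssim(a, b, p))
    vals = [
        fn(rv[d:, :], rv[:-d, :]),   # shift +rows
        fn(rv[:-d, :], rv[d:, :]),   # shift -rows
        fn(rv[:, d:], rv[:, :-d]),   # shift +cols
        fn(rv[:, :-d], rv[:, d:]),   # shift -cols
    ]
    return float(np.mean(vals))


def equivalent_shift(
    r: Image,
    target: float,
    metric: str = "mse",
    pixel_size_um: float | None = None,
    p: SSIMParams | None = None,
) -> float:
    """Smallest whole-pixel self-shift of ``r`` whose metric value is at
    least as bad as ``target``.

    For MSE the shifted metric must reach or exceed the target (larger is
    worse); for SSIM it must fall to or below it.  Returns the shift in μm,
    or ``math.inf`` when no shift up to min(Nl, Nw)/2 crosses the target
    (including the degenerate constant image).
    """
    if metric not in ("mse", "ssim"):
        raise ValueError("metric must be 'mse' or 'ssim'")
    if metric == "mse" and target < 0:
        raise ValueError("MSE target must be non-negative")
    px = pixel_size_um if pixel_size_um is not None else r.pixel_size_um
    if metric == "mse" and target == 0:
        return 0.0
    if metric == "ssim" and target >= 1.0:
        return 0.0
    d_max = min(r.shape) // 2
    for d in range(1, d_max + 1):
        val = shifted_metric(r, d, metric, p)
        if (metric == "mse" and val >= target) or (
            metric == "ssim" and val <= target
        ):
            return d * px
    return math.inf


def equivalent_noise_sigma(target_mse: float, intensity_span: float = 2.0) -> float:
    """Gaussian-noise σ (percent of intensity span) matching a target MSE.

    Adding i.i.d. N(0, σ) noise to every pixel gives an expected MSE of σ²,
    so σ = √MSE; the result is expressed as 100·σ/span (span = 2 for
    [−1, 1] images).  Clipping at the range boundary is not modeled.
    """
    if target_mse < 0:
        raise ValueError("target MSE must be non-negative")
    if intensity_span <= 0:
        raise ValueError("intensity span must be positive")
    return 100.0 * math.sqrt(target_mse) / intensity_span


def compare_images(
    real: Image, syn: Image, p: SSIMParams | None = None,
    pixel_size_um: float | None = None,
) -> MetricReport:
    """Full per-frame report: MSE, SSIM, and their equivalence calibrations."""
    m = mse(real, syn)
    s = ssim(real, syn, p)
    lo, hi = real.intensity_range
    return MetricReport(
        mse=m,
        ssim=s,
        equiv_shift_mse_um=equivalent_shift(real, m, "mse", pixel_size_um, p),
        equiv_shift_ssim_um=equivalent_shift(real, s, "ssim", pixel_size_um, p),
        equiv_noise_pct=equivalent_noise_sigma(m, hi - lo),
    )


def movie_summary(reports: list[MetricReport]) -> dict:
    """Average per-frame metrics across a movie (mean ± sd), the way a
    movie-level table entry is produced: per-frame values first, one
    aggregate number afterwards.  Capped shifts are excluded from the shift
    averages and counted."""
    arr = lambda xs: np.array(xs, dtype=float)  # noqa: E731
    mses = arr([r.mse for r in reports])
    ssims = arr([r.ssim for r in reports])
    sm = arr([r.equiv_shift_mse_um for r in reports])
    ss = arr([r.equiv_shift_ssim_um for r in reports])
    noise = arr([r.equiv_noise_pct for r in reports])
    fin_sm, fin_ss = sm[np.isfinite(sm)], ss[np.isfinite(ss)]
    sd = lambda x: float(x.std(ddof=1)) if x.size > 1 else float("nan")  # noqa: E731
    return {
        "mse_mean": float(mses.mean()), "mse_sd": sd(mses),
        "ssim_mean": float(ssims.mean()), "ssim_sd": sd(ssims),
        "equiv_shift_mse_um_mean": float(fin_sm.mean()) if fin_sm.size else math.inf,
        "equiv_shift_ssim_um_mean": float(fin_ss.mean()) if fin_ss.size else math.inf,
        "equiv_noise_pct_mean": float(noise.mean()),
        "n_frames": len(reports),
        "n_shift_capped": int((~np.isfinite(sm)).sum() + (~np.isfinite(ss)).sum()),
    }
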