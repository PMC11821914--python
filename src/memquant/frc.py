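"""Fourier ring correlation (FRC) resolution estimation.

Two statistically independent images of the same field are correlated ring by
ring in frequency space; the first frequency at which the normalized
correlation drops below a fixed threshold (default 1/7) defines the effective
resolution.  Resolution is reported in biological nm (the pixel size is
divided by the expansion factor upstream), and a blockwise variant tiles the
image and reports the finest resolution across blocks with enough content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, NoSignalError, ParameterError

__all__ = [
    "FRCParams",
    "FRCCurve",
    "FRCResult",
    "frc_curve",
    "frc_resolution",
    "blockwise_frc",
    "split_frames",
]


@dataclass
class FRCParams:
    threshold: float = 1.0 / 7.0  # fixed-threshold criterion
    ring_width_bins: int = 1
    window: bool = True  # 2D Hann apodization before the FFT
    block_size_px: int = 128
    min_block_content: float = 0.2  # fraction of above-background pixels to score a block
    best_rule: str = "min_resolution"

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ParameterError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.block_size_px < 32:
            raise ParameterError(f"block_size_px must be >= 32, got {self.block_size_px}")
        if self.ring_width_bins != 1:
            raise ParameterError("only ring_width_bins=1 is supported")


@dataclass
class FRCCurve:
    frequencies: np.ndarray  # ring spatial frequencies, 1/nm (biological)
    correlations: np.ndarray  # normalized cross-correlation per ring, in [-1, 1]
    n_pixels_per_ring: np.ndarray


@dataclass
class FRCResult:
    resolution_nm: float
    flag: str = "ok"  # "ok" | "limit" (no threshold crossing: Nyquist-bounded)
    per_block: np.ndarray | None = None  # (gy, gx) block resolutions, NaN = unscored
    best_resolution_nm: float | None = None
    curve: FRCCurve | None = None


def _ring_index(n: int) -> np.ndarray:
    """Integer ring index per frequency-plane pixel (DC-centered)."""
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    return np.rint(np.hypot(yy - c, xx - c)).astype(int)


def frc_curve(img_a: np.ndarray, img_b: np.ndarray, bio_pixel_nm: float,
              params: FRCParams | None = None) -> FRCCurve:
    """Compute the FRC curve between two independent acquisitions of one field.

    Both inputs must be the same square 2D shape; rings are one frequency
    sample wide; correlations are clipped to [-1, 1].
    """
    params = params or FRCParams()
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"FRC needs square 2D planes, got {a.shape}")
    if not a.any() or not b.any():
        raise DegenerateInputError("all-zero image has no frequency content to correlate")

    if params.window:
        w = np.hanning(a.shape[0])
        w = np.outer(w, w)
        a = a * w
        b = b * w

    fa = np.fft.fftshift(np.fft.fft2(a))
    fb = np.fft.fftshift(np.fft.fft2(b))
    r = _ring_index(a.shape[0])

    num = np.bincount(r.ravel(), weights=(fa * np.conj(fb)).real.ravel())
    da = np.bincount(r.ravel(), weights=np.abs(fa).ravel() ** 2)
    db = np.bincount(r.ravel(), weights=np.abs(fb).ravel() ** 2)
    npix = np.bincount(r.ravel())

    n = a.shape[0]
    rings = np.arange(1, n // 2 + 1)  # exclude DC, go up to Nyquist
    denom = np.sqrt(da[rings] * db[rings])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num[rings] / np.where(denom > 0, denom, 1.0), 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    freqs = rings / (n * float(bio_pixel_nm))
    return FRCCurve(frequencies=freqs, correlations=corr, n_pixels_per_ring=npix[rings])


def frc_resolution(curve: FRCCurve, bio_pixel_nm: float,
                   params: FRCParams | None = None) -> FRCResult:
    """Resolution = 1/f* at the curve's first downward threshold crossing.

    Linear interpolation between the adjacent rings; if the curve never falls
    below threshold the Nyquist-limited value 2*bio_pixel_nm is returned with
    flag "limit".
    """
    params = params or FRCParams()
    c = curve.correlations
    thr = params.threshold
    nyquist_res = 2.0 * float(bio_pixel_nm)
    if c[0] < thr:
        raise NoSignalError("FRC below threshold at the first ring: no correlated signal")
    below = np.nonzero(c < thr)[0]
    if len(below) == 0:
        return FRCResult(resolution_nm=nyquist_res, flag="limit", curve=curve)
    i = below[0]
    f0, f1 = curve.frequencies[i - 1], curve.frequencies[i]
    c0, c1 = c[i - 1], c[i]
    fstar = f0 + (c0 - thr) / (c0 - c1) * (f1 - f0)
    return FRCResult(resolution_nm=max(1.0 / fstar, nyquist_res), flag="ok", curve=curve)


def _background_threshold(img: np.ndarray) -> float:
    """Above-background cutoff: mean + 2 SD of the lowest-decile pixels."""
    lo = img[img <= np.quantile(img, 0.1)]
    return float(lo.mean() + 2.0 * lo.std())


def blockwise_frc(img_a: np.ndarray, img_b: np.ndarray, bio_pixel_nm: float,
                  params: FRCParams | None = None) -> FRCResult:
    """Tile the image pair into blocks, score content-bearing blocks, report the best.

    "Best" is the minimum (finest) resolution across scored blocks.  Blocks
    with fewer than ``min_block_content`` above-background pixels, or without
    a valid FRC, are left NaN in the per-block map.
    """
    params = params or FRCParams()
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    bs = params.block_size_px
    gy, gx = a.shape[0] // bs, a.shape[1] // bs
    if gy < 1 or gx < 1:
        raise ValueError(f"image {a.shape} smaller than one {bs}px block")

    bg_thr = _background_threshold(a)
    per_block = np.full((gy, gx), np.nan)
    content = np.zeros((gy, gx))
    for iy in range(gy):
        for ix in range(gx):
            sl = (slice(iy * bs, (iy + 1) * bs), slice(ix * bs, (ix + 1) * bs))
            ta, tb = a[sl], b[sl]
            content[iy, ix] = np.mean(ta > bg_thr)
            if content[iy, ix] < params.min_block_content:
                continue
            try:
                res = frc_resolution(frc_curve(ta, tb, bio_pixel_nm, params),
                                     bio_pixel_nm, params)
            except (NoSignalError, DegenerateInputError):
                continue
            per_block[iy, ix] = res.resolution_nm

    if np.isnan(per_block).all():
        raise DegenerateInputError(
            "no scoreable block; content fractions per block:\n" + np.array2string(content))

    # full-image resolution on the largest centered square
    n = min(a.shape)
    y0 = (a.shape[0] - n) // 2
    x0 = (a.shape[1] - n) // 2
    full = frc_resolution(
        frc_curve(a[y0:y0 + n, x0:x0 + n], b[y0:y0 + n, x0:x0 + n], bio_pixel_nm, params),
        bio_pixel_nm, params)
    return FRCResult(resolution_nm=full.resolution_nm, flag=full.flag,
                     per_block=per_block, best_resolution_nm=float(np.nanmin(per_block)),
                     curve=full.curve)


def split_frames(series: np.ndarray, scheme: str = "odd-even"):
    """Split a (t, y, x) series into two half-series by odd/even frame index.

    The paper's protocol for self-consistent FRC on fluctuation data: 40
    captured frames become two sets of 20, preserving order within each half.
    """
    if scheme != "odd-even":
        raise ParameterError(f"unknown split scheme {scheme!r}")
    series = np.asarray(series)
    if series.ndim != 3:
        raise ValueError(f"expected (t, y, x) series, got shape {series.shape}")
    t = series.shape[0]
    if t < 2 or t % 2:
        raise ValueError(f"need an even number of frames >= 2, got {t}")
    return series[0::2], series[1::2]
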