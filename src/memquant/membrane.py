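"""Membrane-label continuity along traced paths and transverse morphometry.

Continuity statistic: intensity is sampled along a traced membrane at uniform
biological arclength steps; a gap is a maximal run of samples more than
``k_sd`` standard deviations below the path mean whose extent exceeds the
image resolution (default 60 nm); percent continuity is the percent of traced
length outside gaps.

Morphometry: a transverse intensity profile is averaged down the long axis of
an oriented box and the tube diameter is the distance between its two wall
peaks, each refined by a 3-point parabolic fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .errors import ParameterError, UnresolvedWallsError
from .model import ImageStack, MembranePath

__all__ = [
    "GapParams",
    "IntensityProfile",
    "GapSet",
    "ContinuityResult",
    "TransverseProfile",
    "sample_path_intensity",
    "detect_gaps",
    "percent_continuity",
    "transverse_profile",
    "diameter_from_profile",
]


@dataclass
class GapParams:
    k_sd: float = 2.0  # threshold multiplier below the path mean
    min_gap_len_nm: float = 60.0  # image resolution in biological nm
    sampling_step_nm: float | None = None  # default: half the lateral bio pixel
    closing_nm: float = 0.0  # merge sub-threshold runs closer than this (0 = off)

    def __post_init__(self):
        if self.k_sd <= 0:
            raise ParameterError(f"k_sd must be > 0, got {self.k_sd}")
        if self.min_gap_len_nm <= 0:
            raise ParameterError(f"min_gap_len_nm must be > 0, got {self.min_gap_len_nm}")


@dataclass
class IntensityProfile:
    arclength_nm: np.ndarray  # uniform samples from 0 to the path length
    intensity: np.ndarray
    mean: float
    sd: float
    step_nm: float
    path_length_nm: float


@dataclass
class GapSet:
    gaps: list  # [(start_nm, end_nm), ...] disjoint, ordered
    flag: str = "ok"  # "ok" | "degenerate-sd"

    @property
    def n_gaps(self) -> int:
        return len(self.gaps)

    @property
    def total_gap_nm(self) -> float:
        return float(sum(e - s for s, e in self.gaps))


@dataclass
class ContinuityResult:
    percent_continuity: float
    n_gaps: int
    total_gap_nm: float
    path_length_nm: float
    gaps: list
    flag: str = "ok"


@dataclass
class TransverseProfile:
    offset_nm: np.ndarray  # signed offset across the structure
    intensity: np.ndarray  # averaged down the box's long axis
    normalized: np.ndarray  # peak = 1
    flag: str = "ok"  # "ok" | "degenerate" (flat profile)


def sample_path_intensity(image, path: MembranePath, params: GapParams | None = None,
                          channel=0, bio_pixel_size_nm=None) -> IntensityProfile:
    """Trilinearly interpolate a channel along a path at uniform arclength steps.

    Mean and SD are computed over this path's samples — the gap threshold is
    relative to the traced membrane itself, not the whole image.
    """
    params = params or GapParams()
    if isinstance(image, ImageStack):
        vol = image.channel(channel)
        bio_px = image.bio_pixel_size_nm
    else:
        vol = np.asarray(image, dtype=float)
        if bio_pixel_size_nm is None:
            raise ParameterError("bio_pixel_size_nm required for a raw array")
        bio_px = np.broadcast_to(np.asarray(bio_pixel_size_nm, float), (3,))
    if vol.ndim == 2:
        vol = vol[None]

    for i, p in enumerate(path.points):
        if np.any(p < -0.5) or np.any(p > np.asarray(vol.shape) - 0.5):
            raise ValueError(f"path vertex {i} at {tuple(p)} lies outside the image")

    step = params.sampling_step_nm or float(min(bio_px[1], bio_px[2]) / 2.0)
    length = path.length_nm
    n = max(2, int(np.floor(length / step)) + 1)
    s = np.arange(n) * step
    coords = np.stack([np.interp(s, path.arclength_nm, path.points[:, k]) for k in range(3)])
    vals = ndimage.map_coordinates(vol, coords, order=1, mode="nearest")
    return IntensityProfile(arclength_nm=s, intensity=vals,
                            mean=float(vals.mean()), sd=float(vals.std()),
                            step_nm=step, path_length_nm=length)


def detect_gaps(profile: IntensityProfile, params: GapParams | None = None) -> GapSet:
    """Find sub-threshold runs along the profile that are longer than the resolution.

    Threshold T = mean - k_sd * sd; a run's extent is measured from its first
    to its last sub-threshold sample plus one step.  Runs are not merged
    across single above-threshold samples unless ``closing_nm`` is set.
    """
    params = params or GapParams()
    if len(profile.intensity) < 2:
        raise ValueError("profile needs >= 2 samples")
    if profile.sd == 0:
        return GapSet([], flag="degenerate-sd")
    thr = profile.mean - params.k_sd * profile.sd
    below = profile.intensity < thr

    # maximal runs of consecutive sub-threshold samples
    edges = np.diff(np.concatenate([[0], below.astype(int), [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]  # exclusive

    step = profile.step_nm
    runs = [(profile.arclength_nm[s] - step / 2.0, profile.arclength_nm[e - 1] + step / 2.0)
            for s, e in zip(starts, ends)]
    if params.closing_nm > 0 and len(runs) > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] <= params.closing_nm:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        runs = merged
    gaps = [(max(0.0, s), min(profile.path_length_nm, e))
            for s, e in runs if (e - s) > params.min_gap_len_nm]
    return GapSet(gaps)


def percent_continuity(profile: IntensityProfile, gaps: GapSet) -> ContinuityResult:
    """Percent of traced arclength outside detected gaps (length-weighted)."""
    total = gaps.total_gap_nm
    pct = 100.0 * (1.0 - total / profile.path_length_nm)
    return ContinuityResult(percent_continuity=float(np.clip(pct, 0.0, 100.0)),
                            n_gaps=gaps.n_gaps, total_gap_nm=total,
                            path_length_nm=profile.path_length_nm,
                            gaps=list(gaps.gaps), flag=gaps.flag)


def transverse_profile(image, center_yx, angle_deg: float, length_px: float,
                       width_px: float, bio_pixel_nm: float = 1.0,
                       channel=0, z: int = 0, step_px: float = 0.25) -> TransverseProfile:
    """Sample an oriented box and average intensity down its long axis.

    ``angle_deg`` is the long-axis direction (0 = +x), ``width_px`` spans the
    structure transversely; the averaged profile is normalized to peak = 1.
    """
    if isinstance(image, ImageStack):
        plane = image.plane(z, channel)
        bio_pixel_nm = float(image.bio_pixel_size_nm[2])
    else:
        plane = np.asarray(image, dtype=float)
    if length_px <= 0 or width_px <= 0:
        raise ParameterError("box length and width must be > 0")

    theta = np.deg2rad(angle_deg)
    u_long = np.array([np.sin(theta), np.cos(theta)])  # (dy, dx)
    u_perp = np.array([np.cos(theta), -np.sin(theta)])
    along = np.arange(-length_px / 2, length_px / 2 + step_px / 2, step_px)
    across = np.arange(-width_px / 2, width_px / 2 + step_px / 2, step_px)
    cy, cx = center_yx
    yy = cy + np.add.outer(across * u_perp[0], along * u_long[0])
    xx = cx + np.add.outer(across * u_perp[1], along * u_long[1])
    vals = ndimage.map_coordinates(plane, [yy, xx], order=1, mode="nearest")
    prof = vals.mean(axis=1)

    lo, hi = prof.min(), prof.max()
    if hi == lo:
        return TransverseProfile(offset_nm=across * bio_pixel_nm, intensity=prof,
                                 normalized=np.ones_like(prof), flag="degenerate")
    return TransverseProfile(offset_nm=across * bio_pixel_nm, intensity=prof,
                             normalized=prof / hi)


def diameter_from_profile(profile: TransverseProfile) -> float:
    """Tube diameter: distance between the two wall peaks of a transverse profile.

    Requires a twin-peaked profile (two local maxima around a local minimum);
    each peak position is refined with a 3-point parabolic fit.  A
    single-peaked profile means the walls are unresolved at the image
    resolution.
    """
    y = profile.normalized
    if profile.flag == "degenerate":
        raise UnresolvedWallsError("flat profile: no wall peaks")
    peaks, props = find_peaks(y, prominence=0.05)
    if len(peaks) < 2:
        raise UnresolvedWallsError("fewer than two wall peaks: structure below resolution")
    order = np.argsort(props["prominences"])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    if y[p1:p2 + 1].min() >= min(y[p1], y[p2]):
        raise UnresolvedWallsError("no local minimum between candidate wall peaks")

    def refine(p):
        if p == 0 or p == len(y) - 1:
            return float(p)
        denom = y[p - 1] - 2 * y[p] + y[p + 1]
        if denom == 0:
            return float(p)
        return p + 0.5 * (y[p - 1] - y[p + 1]) / denom

    x = profile.offset_nm
    dx = x[1] - x[0]
    return float(abs((refine(p2) - refine(p1)) * dx))
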