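"""Expansion-factor estimation and expansion-isotropy (distortion) quantification.

The expansion factor is the mean ratio of corresponding inter-landmark
distances in post- vs pre-expansion images.  Isotropy is quantified by
registering a pre-expansion reference plane to the downscaled post-expansion
plane (rigid, then dense non-rigid), and summarizing the residual deformation
field as a root-mean-square length-measurement-error curve: for point pairs a
distance L apart, the RMS discrepancy between L and the distance after adding
the local displacements.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage
from skimage.registration import optical_flow_tvl1, phase_cross_correlation
from skimage.transform import rescale, rotate

from .errors import ParameterError, RegistrationError
from .model import ImageStack, LandmarkSet

__all__ = [
    "ExpansionEstimate",
    "RigidTransform",
    "DeformationField",
    "RMSCurve",
    "expansion_from_distances",
    "estimate_expansion_factor",
    "downscale_post",
    "register_rigid",
    "register_nonrigid",
    "rms_error_curve",
]


@dataclass
class ExpansionEstimate:
    factor: float  # mean post/pre distance ratio
    per_pair_ratios: np.ndarray
    sd: float
    ci95: tuple  # normal-theory 95% CI on the mean


@dataclass
class RigidTransform:
    angle_deg: float
    shift_yx: tuple
    score: float  # normalized cross-correlation at the optimum


@dataclass
class DeformationField:
    """Dense displacement field (pre -> post residual) in biological nm."""

    dy_nm: np.ndarray
    dx_nm: np.ndarray
    bio_pixel_nm: float
    mask: np.ndarray | None = None  # where the field is trusted; zero outside

    @property
    def magnitude_nm(self) -> np.ndarray:
        return np.hypot(self.dy_nm, self.dx_nm)


@dataclass
class RMSCurve:
    length_um: np.ndarray  # measurement length per bin, biological micrometres
    rms_um: np.ndarray
    sd_um: np.ndarray
    n_pairs: np.ndarray


def expansion_from_distances(pre_distances, post_distances) -> ExpansionEstimate:
    """Mean of per-distance post/pre ratios, with dispersion."""
    dpre = np.asarray(pre_distances, dtype=float)
    dpost = np.asarray(post_distances, dtype=float)
    if dpre.shape != dpost.shape or dpre.size == 0:
        raise ValueError("distance lists must be equal-length and non-empty")
    if np.any(dpre <= 0):
        raise ParameterError("coincident landmarks: zero pre-expansion distance")
    ratios = dpost / dpre
    factor = float(ratios.mean())
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    half = 1.96 * sd / np.sqrt(ratios.size)
    return ExpansionEstimate(factor=factor, per_pair_ratios=ratios, sd=sd,
                             ci95=(factor - half, factor + half))


def estimate_expansion_factor(landmarks: LandmarkSet,
                              pre_pixel_size_nm=1.0,
                              post_pixel_size_nm=1.0) -> ExpansionEstimate:
    """Expansion factor from all C(n, 2) inter-landmark physical distances."""
    ps_pre = np.broadcast_to(np.asarray(pre_pixel_size_nm, float), (3,))
    ps_post = np.broadcast_to(np.asarray(post_pixel_size_nm, float), (3,))
    pre = landmarks.pre * ps_pre
    post = landmarks.post * ps_post
    idx = list(combinations(range(landmarks.n_pairs), 2))
    dpre = np.array([np.linalg.norm(pre[i] - pre[j]) for i, j in idx])
    dpost = np.array([np.linalg.norm(post[i] - post[j]) for i, j in idx])
    return expansion_from_distances(dpre, dpost)


def downscale_post(post, factor: float, shape=None) -> np.ndarray:
    """Bring a post-expansion plane into pre-expansion coordinates (1/factor),
    center-cropped/padded to ``shape`` when given."""
    post = post.plane() if isinstance(post, ImageStack) else np.asarray(post, float)
    if factor != 1.0:
        post = rescale(post, 1.0 / factor, anti_aliasing=True, preserve_range=True)
    return _fit_to_shape(post, shape) if shape is not None else post


def _fit_to_shape(img: np.ndarray, shape) -> np.ndarray:
    """Center-crop / zero-pad to the target shape."""
    out = np.zeros(shape, dtype=img.dtype)
    sy = min(img.shape[0], shape[0])
    sx = min(img.shape[1], shape[1])
    oy, ox = (shape[0] - sy) // 2, (shape[1] - sx) // 2
    iy, ix = (img.shape[0] - sy) // 2, (img.shape[1] - sx) // 2
    out[oy:oy + sy, ox:ox + sx] = img[iy:iy + sy, ix:ix + sx]
    return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def register_rigid(pre, post, factor: float = 1.0, angle_range_deg: float = 10.0,
                   angle_step_deg: float = 0.25, min_score: float = 0.2):
    """Rigid alignment of the post image (downscaled by 1/factor) onto the pre image.

    Grid search over rotation with subpixel translation by phase correlation
    at each angle, scored by normalized cross-correlation.  Returns the
    transform and the aligned post image.
    """
    pre = pre.plane() if isinstance(pre, ImageStack) else np.asarray(pre, float)
    post = post.plane() if isinstance(post, ImageStack) else np.asarray(post, float)
    if factor < 1:
        raise ParameterError(f"factor must be >= 1, got {factor}")
    post = downscale_post(post, factor, pre.shape)

    best = None
    angles = np.arange(-angle_range_deg, angle_range_deg + angle_step_deg / 2, angle_step_deg)
    for ang in angles:
        rot = rotate(post, ang, preserve_range=True) if ang else post
        shift, _, _ = phase_cross_correlation(pre, rot, upsample_factor=10,
                                              normalization=None)
        cand = ndimage.shift(rot, shift, order=1)
        score = _ncc(pre, cand)
        if best is None or score > best[0]:
            best = (score, float(ang), tuple(float(s) for s in shift), cand)
    score, ang, shift, aligned = best
    if score < min_score:
        raise RegistrationError(f"peak correlation {score:.3f} < {min_score}: no reliable alignment")
    return RigidTransform(angle_deg=ang, shift_yx=shift, score=score), aligned


def register_nonrigid(pre, post_aligned, bio_pixel_nm: float = 1.0,
                      grid_spacing_px: int = 16) -> DeformationField:
    """Dense non-rigid residual field between rigidly aligned pre/post planes.

    TV-L1 variational optical flow on lightly band-limited images (both
    inputs get a 1 px Gaussian blur, reducing the bandwidth mismatch left by
    the post image's downscaling anti-alias filter); the field maps the pre
    image onto the aligned post image and is zeroed outside the pre image's
    content mask.
    """
    pre = pre.plane() if isinstance(pre, ImageStack) else np.asarray(pre, float)
    post = post_aligned.plane() if isinstance(post_aligned, ImageStack) \
        else np.asarray(post_aligned, float)
    if pre.shape != post.shape:
        raise ValueError(f"shape mismatch: {pre.shape} vs {post.shape}")
    flow = optical_flow_tvl1(ndimage.gaussian_filter(pre, 1.0),
                             ndimage.gaussian_filter(post, 1.0))
    if not np.isfinite(flow).all():
        raise RegistrationError("optical flow diverged (non-finite displacements)")
    dy, dx = flow[0], flow[1]

    lo = pre[pre <= np.quantile(pre, 0.1)]
    mask = pre > lo.mean() + 2 * lo.std()
    mask = ndimage.binary_dilation(mask, iterations=2)
    dy = np.where(mask, dy, 0.0)
    dx = np.where(mask, dx, 0.0)
    return DeformationField(dy_nm=dy * bio_pixel_nm, dx_nm=dx * bio_pixel_nm,
                            bio_pixel_nm=float(bio_pixel_nm), mask=mask)


def default_length_bins_nm(field: DeformationField, n_bins: int = 10) -> np.ndarray:
    """10 log-spaced measurement lengths from 1 um to half the field extent."""
    extent_nm = min(field.dy_nm.shape) * field.bio_pixel_nm
    return np.geomspace(1000.0, extent_nm / 2.0, n_bins)


def rms_error_curve(field: DeformationField, n_pairs_per_bin: int = 1000,
                    bins_nm=None, mask=None, seed: int = 0) -> RMSCurve:
    """RMS length-measurement error vs measurement length from a deformation field.

    For each measurement length L, point pairs separated by L are sampled
    inside the mask; each pair's error is | |(p2+u2)-(p1+u1)| - L |.  Global
    translations of the field cancel exactly; a uniform 1% misscaling gives
    rms(L) = 0.01 L.
    """
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = field.mask if field.mask is not None else np.ones(field.dy_nm.shape, bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ParameterError("empty sampling mask")
    if bins_nm is None:
        bins_nm = default_length_bins_nm(field)
    bins_nm = np.asarray(bins_nm, float)

    px = field.bio_pixel_nm
    pts = np.argwhere(mask)  # (m, 2) int
    h, w = mask.shape

    rms, sd, npairs = [], [], []
    for L in bins_nm:
        errs = []
        tries = 0
        while len(errs) < n_pairs_per_bin and tries < 30 * n_pairs_per_bin:
            batch = min(4 * n_pairs_per_bin, 30 * n_pairs_per_bin - tries)
            tries += batch
            p1 = pts[rng.integers(0, len(pts), batch)].astype(float)
            theta = rng.uniform(0, 2 * np.pi, batch)
            p2 = p1 + (L / px) * np.column_stack([np.sin(theta), np.cos(theta)])
            ok = ((p2[:, 0] >= 0) & (p2[:, 0] <= h - 1) &
                  (p2[:, 1] >= 0) & (p2[:, 1] <= w - 1))
            ok &= mask[np.clip(np.rint(p2[:, 0]).astype(int), 0, h - 1),
                       np.clip(np.rint(p2[:, 1]).astype(int), 0, w - 1)]
            if not ok.any():
                continue
            p1, p2 = p1[ok], p2[ok]
            u1 = np.stack([ndimage.map_coordinates(field.dy_nm, p1.T, order=1),
                           ndimage.map_coordinates(field.dx_nm, p1.T, order=1)], axis=1)
            u2 = np.stack([ndimage.map_coordinates(field.dy_nm, p2.T, order=1),
                           ndimage.map_coordinates(field.dx_nm, p2.T, order=1)], axis=1)
            d_after = np.linalg.norm((p2 - p1) * px + (u2 - u1), axis=1)
            errs.extend(np.abs(d_after - L))
        errs = np.asarray(errs[:n_pairs_per_bin])
        npairs.append(len(errs))
        if len(errs):
            rms.append(np.sqrt(np.mean(errs ** 2)))
            sd.append(errs.std())
        else:
            rms.append(np.nan)
            sd.append(np.nan)
    return RMSCurve(length_um=bins_nm / 1000.0, rms_um=np.asarray(rms) / 1000.0,
                    sd_um=np.asarray(sd) / 1000.0, n_pairs=np.asarray(npairs))
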