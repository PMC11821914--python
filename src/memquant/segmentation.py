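"""Segmentation/tracing agreement (Rand score) and marker colocalization.

The Rand score counts voxel pairs on which two labelings agree (same object
in both, or different objects in both) out of all pairs, computed from
label-contingency sums rather than pair enumeration.  A score of 1 means the
two labelings induce identical partitions on the evaluated voxel set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, ParameterError
from .model import MembranePath

__all__ = [
    "LabelVolume",
    "RandResult",
    "rand_score",
    "trace_to_labels",
    "colocalization_fraction",
]


@dataclass
class LabelVolume:
    """Integer label grid; 0 = background, >0 = object ids."""

    data: np.ndarray
    voxel_size_nm: tuple | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")


@dataclass
class RandResult:
    score: float
    variant: str  # "plain" | "adapted"
    n_agree_same: int  # pairs co-labeled in both
    n_agree_diff: int  # pairs separated in both
    n_disagree: int
    restricted_to_foreground: bool


def _as_labels(vol) -> np.ndarray:
    return vol.data if isinstance(vol, LabelVolume) else np.asarray(vol)


def _contingency(la: np.ndarray, lb: np.ndarray):
    """Contingency counts n_ij plus the marginals, via a flat joint encoding."""
    ua, ia = np.unique(la, return_inverse=True)
    ub, ib = np.unique(lb, return_inverse=True)
    joint = ia.astype(np.int64) * len(ub) + ib
    nij = np.bincount(joint, minlength=len(ua) * len(ub)).reshape(len(ua), len(ub))
    return nij, nij.sum(axis=1), nij.sum(axis=0)


def rand_score(seg_a, seg_b, foreground_restricted: bool = True,
               variant: str = "plain") -> RandResult:
    """Pair-counting Rand agreement between two label volumes.

    With ``foreground_restricted`` only voxels labeled foreground in
    ``seg_b`` (the designated ground truth) are evaluated.  ``variant``:

    * ``"plain"`` — Rand index, (agreeing pairs) / (all pairs);
    * ``"adapted"`` — the connectomics adapted-Rand F-score
      2*sum n_ij^2 / (sum a_i^2 + sum b_j^2) over the evaluated voxels.
    """
    a = _as_labels(seg_a)
    b = _as_labels(seg_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if variant not in ("plain", "adapted"):
        raise ParameterError(f"unknown Rand variant {variant!r}")
    sel = (b.ravel() > 0) if foreground_restricted else slice(None)
    la = a.ravel()[sel]
    lb = b.ravel()[sel]
    n = la.size
    if n == 0:
        raise DegenerateInputError("empty evaluated voxel set")

    nij, ai, bj = _contingency(la, lb)
    sum_ij = float((nij.astype(np.int64) ** 2).sum())
    sum_a = float((ai.astype(np.int64) ** 2).sum())
    sum_b = float((bj.astype(np.int64) ** 2).sum())

    pairs = n * (n - 1) / 2.0
    same_both = (sum_ij - n) / 2.0  # sum C(n_ij, 2)
    same_a = (sum_a - n) / 2.0
    same_b = (sum_b - n) / 2.0
    diff_both = pairs - same_a - same_b + same_both
    agree = same_both + diff_both

    if variant == "plain":
        score = agree / pairs if pairs > 0 else 1.0
    else:
        score = 2.0 * sum_ij / (sum_a + sum_b)
    return RandResult(score=float(score), variant=variant,
                      n_agree_same=int(round(same_both)),
                      n_agree_diff=int(round(diff_both)),
                      n_disagree=int(round(pairs - agree)),
                      restricted_to_foreground=bool(foreground_restricted))


def trace_to_labels(traces, shape, brush_radius_px: float):
    """Rasterize traced centerlines as tubes for Rand comparison of tracings.

    Each trace becomes one label painted as all voxels within
    ``brush_radius_px`` of its densified centerline (the paper's tracing
    annotations used a fixed brush size).  Where tubes overlap, the later
    trace wins; the fraction of painted voxels claimed more than once is
    returned alongside the volume.
    """
    vol = np.zeros(shape, dtype=np.int32)
    claimed = np.zeros(shape, dtype=np.int8)
    for i, trace in enumerate(traces):
        pts = trace.points if isinstance(trace, MembranePath) else np.asarray(trace, float)
        if np.any(pts < -0.5) or np.any(pts > np.asarray(shape) - 0.5):
            raise ValueError(f"trace {i} leaves the volume")
        # densify the polyline so no voxel is skipped
        dense = [pts[0]]
        for p0, p1 in zip(pts[:-1], pts[1:]):
            nseg = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / 0.3)))
            dense.append(np.linspace(p0, p1, nseg)[1:])
        dense = np.vstack([np.atleast_2d(d) for d in dense])
        seeds = np.zeros(shape, dtype=bool)
        idx = tuple(np.clip(np.rint(dense[:, k]).astype(int), 0, shape[k] - 1)
                    for k in range(len(shape)))
        seeds[idx] = True
        dist = ndimage.distance_transform_edt(~seeds)
        tube = dist <= brush_radius_px
        claimed[tube] += 1
        vol[tube] = i + 1
    painted = claimed > 0
    overlap_fraction = float((claimed > 1).sum() / painted.sum()) if painted.any() else 0.0
    return LabelVolume(vol), overlap_fraction


def colocalization_fraction(reference_mask, probe_image, threshold_method: str = "otsu",
                            percentile: float = 90.0, fixed_threshold: float | None = None) -> float:
    """Fraction of reference-marker pixels that are also probe-positive.

    The probe channel is thresholded (Otsu by default, or a fixed percentile
    / explicit value) and the returned fraction is
    |reference AND probe+| / |reference|.
    """
    ref = np.asarray(reference_mask).astype(bool)
    probe = np.asarray(probe_image, dtype=float)
    if ref.shape != probe.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {probe.shape}")
    if not ref.any():
        raise DegenerateInputError("empty reference mask")
    if fixed_threshold is not None:
        thr = float(fixed_threshold)
    elif threshold_method == "otsu":
        thr = float(threshold_otsu(probe))
    elif threshold_method == "percentile":
        thr = float(np.percentile(probe, percentile))
    else:
        raise ParameterError(f"unknown threshold method {threshold_method!r}")
    pos = probe > thr
    return float((ref & pos).sum() / ref.sum())
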