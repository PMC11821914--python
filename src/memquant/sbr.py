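"""Signal-to-background (S/B) depth profiles.

The mean labeled-plane intensity of each XY plane is divided by a single
scalar background estimated from empty-gel reference acquisitions taken with
matched imaging settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .model import ImageStack

__all__ = ["SBRProfile", "background_level", "sbr_depth_profile"]


@dataclass
class SBRProfile:
    z_um: np.ndarray  # plane depth, biological micrometres
    mean_signal: np.ndarray  # per-plane mean over all pixels
    background_mean: float
    sbr: np.ndarray  # mean_signal / background_mean


def background_level(empty_gel_images) -> float:
    """Grand mean intensity over all pixels of all empty-gel reference images.

    Images of unequal size contribute in proportion to their pixel count
    (pixel-weighted mean).
    """
    if not empty_gel_images:
        raise ParameterError("need at least one empty-gel image")
    tot = 0.0
    npx = 0
    for img in empty_gel_images:
        arr = img.data if isinstance(img, ImageStack) else np.asarray(img, dtype=float)
        tot += float(arr.sum())
        npx += arr.size
    return tot / npx


def sbr_depth_profile(volume, background: float, channel=0,
                      bio_pixel_z_nm: float | None = None) -> SBRProfile:
    """Per-plane mean intensity divided by the background scalar.

    ``volume`` may be an ImageStack (z spacing taken from its biological
    units) or a raw (z, y, x) array with ``bio_pixel_z_nm`` supplied.
    """
    if background <= 0:
        raise ParameterError(f"background must be > 0, got {background}")
    if isinstance(volume, ImageStack):
        arr = volume.channel(channel)
        dz_nm = float(volume.bio_pixel_size_nm[0])
    else:
        arr = np.asarray(volume, dtype=float)
        dz_nm = float(bio_pixel_z_nm) if bio_pixel_z_nm else 1.0
    if arr.ndim != 3:
        raise ValueError(f"expected a (z, y, x) volume, got shape {arr.shape}")
    mean_signal = arr.mean(axis=(1, 2))
    z_um = np.arange(arr.shape[0]) * dz_nm / 1000.0
    return SBRProfile(z_um=z_um, mean_signal=mean_signal,
                      background_mean=float(background),
                      sbr=mean_signal / background)
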