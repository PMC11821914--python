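"""Shared data model: image stacks with physical units, traced paths, landmarks.

Conventions used throughout the package:

* axis order is ``(z, y, x)`` for volumes and ``(t, y, x)`` for time series;
  coordinates are 0-based and pixel-centered;
* ``pixel_size_nm`` is the physical voxel size of the *expanded* sample;
* biological units are physical units divided by the linear expansion factor,
  which is how all results are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UnitError

__all__ = ["ImageStack", "MembranePath", "LandmarkSet", "to_biological"]


def to_biological(length_nm, expansion_factor: float):
    """Convert a physical (expanded-sample) length in nm to biological nm.

    E.g. the ~500 nm axial extent of a confocal point-spread function maps to
    500 / 4 = 125 nm in biological units at 4x expansion.
    """
    if expansion_factor < 1:
        raise UnitError(f"expansion_factor must be >= 1, got {expansion_factor}")
    return length_nm / expansion_factor


@dataclass
class ImageStack:
    """A multi-channel intensity grid with physical units.

    ``data`` is stored as ``(C, Z, Y, X)`` (or ``(C, T, Y, X)`` for a time
    series, with ``axes='ctyx'``).  2D and single-channel inputs are promoted
    on construction.
    """

    data: np.ndarray
    pixel_size_nm: tuple  # (z, y, x), nm of the expanded sample
    expansion_factor: float = 1.0
    channel_names: tuple = ()
    axes: str = "czyx"

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 2:
            data = data[None, None]
        elif data.ndim == 3:
            data = data[None]
        elif data.ndim != 4:
            raise ValueError(f"expected 2-4 dims, got shape {data.shape}")
        if not np.isfinite(data).all():
            raise ValueError("image data contains non-finite values")
        # camera offsets can produce small negatives; clip on load
        self.data = np.clip(data, 0, None)

        ps = tuple(float(p) for p in np.atleast_1d(self.pixel_size_nm))
        if len(ps) == 1:
            ps = ps * 3
        if len(ps) == 2:  # (y, x) given for a 2D plane: use y for z
            ps = (ps[0],) + ps
        if len(ps) != 3 or any(p <= 0 for p in ps):
            raise UnitError(f"pixel_size_nm must be 3 positive values, got {self.pixel_size_nm}")
        self.pixel_size_nm = ps

        if self.expansion_factor < 1:
            raise UnitError(f"expansion_factor must be >= 1, got {self.expansion_factor}")
        self.expansion_factor = float(self.expansion_factor)

        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        else:
            self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match number of channels")
        if self.axes not in ("czyx", "ctyx"):
            raise ValueError(f"axes must be 'czyx' or 'ctyx', got {self.axes!r}")

    # -- units ------------------------------------------------------------
    @property
    def bio_pixel_size_nm(self) -> np.ndarray:
        """(z, y, x) voxel size in biological nm (physical / expansion factor)."""
        return np.asarray(self.pixel_size_nm) / self.expansion_factor

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        """Spatial (or temporal) shape without the channel axis."""
        return self.data.shape[1:]

    @property
    def is_timeseries(self) -> bool:
        return "t" in self.axes

    # -- access -----------------------------------------------------------
    def channel(self, which=0) -> np.ndarray:
        """Return one channel as a (Z, Y, X) / (T, Y, X) array."""
        if isinstance(which, str):
            try:
                which = self.channel_names.index(which)
            except ValueError:
                raise KeyError(f"no channel named {which!r}; have {self.channel_names}")
        return self.data[which]

    def plane(self, z: int = 0, channel=0) -> np.ndarray:
        return self.channel(channel)[z]


@dataclass
class MembranePath:
    """Ordered polyline along a traced membrane, with biological arclength."""

    points: np.ndarray  # (n, 3) float, (z, y, x) sub-pixel coordinates
    arclength_nm: np.ndarray  # (n,) cumulative biological arclength, starts at 0
    source: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.arclength_nm = np.asarray(self.arclength_nm, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("a path needs >= 2 (z, y, x) points")
        if len(self.arclength_nm) != len(self.points):
            raise ValueError("arclength and points length mismatch")
        if not np.all(np.diff(self.arclength_nm) > 0):
            raise ValueError("arclength must be strictly increasing (no repeated points)")

    @classmethod
    def from_pixel_points(cls, points, bio_pixel_size_nm, source: str = "") -> "MembranePath":
        """Build a path from pixel coordinates, computing biological arclength."""
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or len(points) < 2:
            raise ValueError("a path needs >= 2 points")
        if points.shape[1] == 2:  # (y, x) -> z = 0
            points = np.column_stack([np.zeros(len(points)), points])
        ps = np.asarray(bio_pixel_size_nm, dtype=float)
        if ps.size == 1:
            ps = np.repeat(ps, 3)
        seg = np.linalg.norm(np.diff(points, axis=0) * ps, axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive path points must be distinct")
        return cls(points, np.concatenate([[0.0], np.cumsum(seg)]), source=source)

    @property
    def length_nm(self) -> float:
        return float(self.arclength_nm[-1])


@dataclass
class LandmarkSet:
    """Matched landmark coordinates in a pre/post-expansion image pair (pixels)."""

    pre: np.ndarray  # (n, 3) pixel coordinates in the pre image
    post: np.ndarray  # (n, 3) pixel coordinates in the post image

    def __post_init__(self):
        self.pre = np.atleast_2d(np.asarray(self.pre, dtype=float))
        self.post = np.atleast_2d(np.asarray(self.post, dtype=float))
        for name, arr in (("pre", self.pre), ("post", self.post)):
            if arr.ndim != 2 or arr.shape[1] not in (2, 3):
                raise ValueError(f"{name} landmarks must be (n, 3) or (n, 2)")
        if self.pre.shape[1] == 2:
            self.pre = np.column_stack([np.zeros(len(self.pre)), self.pre])
        if self.post.shape[1] == 2:
            self.post = np.column_stack([np.zeros(len(self.post)), self.post])
        if self.pre.shape != self.post.shape:
            raise ValueError("pre and post landmark counts differ")
        if len(self.pre) < 2:
            raise ValueError("need >= 2 landmark pairs for distance-ratio estimation")
        if not (np.isfinite(self.pre).all() and np.isfinite(self.post).all()):
            raise ValueError("landmark coordinates must be finite")

    @property
    def n_pairs(self) -> int:
        return len(self.pre)
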