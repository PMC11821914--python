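"""Shared fixtures: small phantoms and annotation-file builders."""

import struct

import numpy as np
import pytest

from memquant import phantom


def straight_tube_spec(shape=(12, 32, 128), radius_nm=150.0, shell_nm=40.0,
                       seed=0, **kw):
    """One near-straight tube spanning x at mid-depth."""
    nz, ny, nx = shape
    pts = np.array([[nz / 2, ny / 2, 2.0],
                    [nz / 2, ny / 2, nx / 2],
                    [nz / 2, ny / 2, nx - 3.0]])
    tube = phantom.TubeSpec(pts, radius_nm=radius_nm, shell_thickness_nm=shell_nm)
    return phantom.PhantomSpec(shape=shape, tubes=[tube], fill_channel=False,
                               seed=seed, **kw)


def cilium_spec(seed, nx=420):
    """A long, gently wandering cilium-like tube for continuity experiments."""
    rng = np.random.default_rng(seed)
    x = np.linspace(2, nx - 3, 7)
    y = 16 + rng.normal(0, 0.5, 7)
    z = 6 + rng.normal(0, 0.5, 7)
    tube = phantom.TubeSpec(np.column_stack([z, y, x]), radius_nm=150.0,
                            shell_thickness_nm=40.0)
    return phantom.PhantomSpec(shape=(12, 32, nx), tubes=[tube],
                               fill_channel=False, seed=seed)


@pytest.fixture(scope="session")
def straight_phantom():
    return phantom.make_tube_phantom(straight_tube_spec())


@pytest.fixture(scope="session")
def default_phantom():
    """The generator's default mixed bundle at a reduced footprint."""
    return phantom.make_tube_phantom(phantom.PhantomSpec(shape=(8, 128, 128), seed=1))


def make_imagej_roi(ys, xs, roi_type=5) -> bytes:
    """Assemble an ImageJ .roi blob per the published binary layout."""
    n = len(xs)
    top, left = min(ys), min(xs)
    hdr = bytearray(64)
    hdr[0:4] = b"Iout"
    struct.pack_into(">h", hdr, 4, 227)  # version
    hdr[6] = roi_type
    struct.pack_into(">hhhhh", hdr, 8, top, left, max(ys) + 1, max(xs) + 1, n)
    body = b"".join(struct.pack(">h", x - left) for x in xs)
    body += b"".join(struct.pack(">h", y - top) for y in ys)
    return bytes(hdr) + body
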