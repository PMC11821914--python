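"""Synthetic membrane phantoms with complete ground truth.

Generates tubular membrane geometry (thin shells around smooth centerlines:
unmyelinated axons, myelinated axons with thicker/brighter sheaths, cilia),
renders a "membrane" shell channel and an optional lumen "fill" channel,
blurs with an anisotropic Gaussian PSF, adds Poisson photon noise plus
Gaussian read noise and constant background, and carries full ground truth:
centerline paths, inserted gap intervals, landmark pairs, and deformation
fields.  Every operation is bit-reproducible for a fixed (spec, seed).

Background is spatially constant — real neuropil background varies; see the
methods note for what this simplification implies for green tests.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate, ndimage
from scipy.spatial import cKDTree

from .distortion import DeformationField
from .errors import ParameterError
from .model import ImageStack, LandmarkSet, MembranePath

__all__ = [
    "TubeSpec",
    "PhantomSpec",
    "PhantomVolume",
    "make_tube_phantom",
    "surface_path",
    "insert_gaps",
    "render_image",
    "make_fluctuation_series",
    "make_distorted_pair",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class TubeSpec:
    """One tubular structure: centerline control points plus shell geometry."""

    points_px: np.ndarray  # (k, 3) control points, (z, y, x) pixel coordinates
    radius_nm: float = 150.0
    shell_thickness_nm: float = 40.0
    myelinated: bool = False  # 3x thicker, 2x brighter shell
    brightness: float = 1.0

    def __post_init__(self):
        self.points_px = np.atleast_2d(np.asarray(self.points_px, dtype=float))
        if self.radius_nm <= self.shell_thickness_nm / 2:
            raise ParameterError("tube radius must exceed half the shell thickness")


@dataclass
class PhantomSpec:
    shape: tuple = (64, 256, 256)  # (z, y, x) voxels
    bio_pixel_nm: tuple = (25.0, 25.0, 25.0)
    expansion_factor: float = 4.0
    tubes: list | None = None  # None -> a default mixed bundle
    fill_channel: bool = True
    psf_fwhm_nm: tuple = (500.0, 250.0)  # (axial, lateral), physical (expanded) nm
    photon_scale: float = 200.0  # expected peak photons
    gauss_read_noise: float = 2.0
    background_level: float = 5.0
    gap_fraction: float = 0.0
    min_gap_len_nm: float = 200.0  # >= 3x the biological PSF FWHM, so gaps resolve
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.bio_pixel_nm = tuple(float(p) for p in np.broadcast_to(
            np.asarray(self.bio_pixel_nm, float), (3,)))
        if any(p <= 0 for p in self.bio_pixel_nm):
            raise ParameterError("bio_pixel_nm must be positive")
        if not 0 <= self.gap_fraction < 1:
            raise ParameterError(f"gap fraction must be in [0, 1), got {self.gap_fraction}")
        if any(f <= 0 for f in self.psf_fwhm_nm):
            raise ParameterError("PSF FWHM must be positive")

    @property
    def psf_sigma_px(self) -> np.ndarray:
        """(z, y, x) PSF sigma in voxels, biological units."""
        ax, lat = self.psf_fwhm_nm
        sig_bio = np.array([ax, lat, lat]) * FWHM_TO_SIGMA / self.expansion_factor
        return sig_bio / np.asarray(self.bio_pixel_nm)


@dataclass
class PhantomVolume:
    """Rendered noiseless geometry plus every piece of ground truth."""

    spec: PhantomSpec
    images: ImageStack  # noiseless geometry, channels ("membrane"[, "fill"])
    shell_mask: np.ndarray  # bool, membrane shell voxels
    paths_truth: list  # MembranePath centerlines
    gaps_truth: list  # per path: [(start_nm, end_nm), ...]
    tubes: list = field(default_factory=list)  # resolved TubeSpec list
    landmarks_truth: LandmarkSet | None = None
    deformation_truth: DeformationField | None = None
    # per tube: (voxel index arrays (z, y, x), arclength_nm of nearest centerline point)
    voxel_arclength: list = field(default_factory=list, repr=False)

    def membrane(self) -> np.ndarray:
        return self.images.channel("membrane")


def _default_tubes(shape, bio_pixel_nm, rng) -> list:
    """A small mixed bundle spanning x: cilium, unmyelinated and myelinated axon."""
    nz, ny, nx = shape
    tubes = []
    for i, (r, t, myel) in enumerate([(150.0, 40.0, False),
                                      (200.0, 40.0, False),
                                      (400.0, 120.0, True)]):
        n_ctrl = 7
        x = np.linspace(2, nx - 3, n_ctrl)
        y = ny * (i + 1) / 4.0 + rng.normal(0, ny * 0.02, n_ctrl)
        z = nz / 2.0 + rng.normal(0, nz * 0.05, n_ctrl)
        tubes.append(TubeSpec(np.column_stack([z, y, x]), radius_nm=r,
                              shell_thickness_nm=t, myelinated=myel))
    return tubes


def _densify(points_px: np.ndarray, step_px: float) -> np.ndarray:
    """Resample a centerline at ~step_px spacing (cubic spline if >= 4 points)."""
    pts = points_px
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    n = max(4, int(np.ceil(total / step_px)) + 1)
    if len(pts) >= 4:
        tck, _ = interpolate.splprep(pts.T, s=0, k=3)
        u = np.linspace(0, 1, n)
        return np.stack(interpolate.splev(u, tck), axis=1)
    u = np.concatenate([[0], np.cumsum(seg)]) / total
    uu = np.linspace(0, 1, n)
    return np.stack([np.interp(uu, u, pts[:, k]) for k in range(3)], axis=1)


def make_tube_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Render the noiseless shell (and lumen fill) geometry for all tubes.

    Shell rendering is by distance to the densified centerline:
    |d - r| < thickness/2, antialiased with a linear falloff over one lateral
    voxel.  Tubes that leave the volume are clipped with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    tubes = spec.tubes if spec.tubes is not None else _default_tubes(
        spec.shape, spec.bio_pixel_nm, rng)

    shape = spec.shape
    px = np.asarray(spec.bio_pixel_nm)
    aa = float(min(px[1], px[2]))  # antialias width: one lateral voxel
    membrane = np.zeros(shape)
    fill = np.zeros(shape) if spec.fill_channel else None
    shell_mask = np.zeros(shape, bool)
    paths, voxel_arc = [], []

    for tube in tubes:
        r = tube.radius_nm
        t = tube.shell_thickness_nm * (3.0 if tube.myelinated else 1.0)
        bright = tube.brightness * (2.0 if tube.myelinated else 1.0)
        center = _densify(tube.points_px, 0.4)  # ~0.4 px steps
        if np.any(center < -0.5) or np.any(center > np.asarray(shape) - 0.5):
            warnings.warn("tube centerline exits the volume; clipping", stacklevel=2)
        center_nm = center * px
        arc = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(center_nm, axis=0), axis=1))])

        margin = (r + t / 2 + 2 * aa) / px
        lo = np.maximum(np.floor(center.min(axis=0) - margin).astype(int), 0)
        hi = np.minimum(np.ceil(center.max(axis=0) + margin).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)],
                                 indexing="ij")
        coords_nm = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3) * px
        tree = cKDTree(center_nm)
        d, nearest = tree.query(coords_nm)

        shell = np.clip((t / 2 + aa - np.abs(d - r)) / aa, 0.0, 1.0)
        sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        shell3 = shell.reshape(zz.shape)
        membrane[sub] = np.maximum(membrane[sub], bright * shell3)
        shell_mask[sub] |= shell3 >= 0.5
        if fill is not None:
            lum = np.clip((r - t / 2 - d) / aa + 1.0, 0.0, 1.0)
            fill[sub] = np.maximum(fill[sub], lum.reshape(zz.shape))

        keep = shell > 0
        vox = (zz.ravel()[keep], yy.ravel()[keep], xx.ravel()[keep])
        voxel_arc.append((vox, arc[nearest[keep]]))
        paths.append(MembranePath.from_pixel_points(center[::4], px, source="phantom-truth"))

    channels = [membrane] + ([fill] if fill is not None else [])
    names = ("membrane", "fill")[: len(channels)]
    stack = ImageStack(np.stack(channels),
                       pixel_size_nm=tuple(p * spec.expansion_factor for p in px),
                       expansion_factor=spec.expansion_factor,
                       channel_names=names)
    return PhantomVolume(spec=spec, images=stack, shell_mask=shell_mask,
                         paths_truth=paths, gaps_truth=[[] for _ in paths],
                         tubes=list(tubes), voxel_arclength=voxel_arc)


def surface_path(phantom: PhantomVolume, tube_index: int = 0,
                 direction=(0.0, 1.0, 0.0)) -> MembranePath:
    """A trace along the membrane wall: the centerline offset radially by the
    tube radius, in ``direction`` projected perpendicular to the local tangent.

    This is what a manual membrane trace follows (the label lives on the
    shell, not the lumen axis); it shares the centerline's arclength
    parameterization, so gap-truth intervals apply to it directly.
    """
    tube = phantom.tubes[tube_index]
    path = phantom.paths_truth[tube_index]
    px = np.asarray(phantom.spec.bio_pixel_nm)
    pts_nm = path.points * px
    tang = np.gradient(pts_nm, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    d = np.broadcast_to(np.asarray(direction, float), pts_nm.shape)
    normal = d - (d * tang).sum(axis=1, keepdims=True) * tang
    norms = np.linalg.norm(normal, axis=1, keepdims=True)
    if np.any(norms < 1e-9):
        raise ParameterError("offset direction parallel to the tube tangent")
    normal /= norms
    offset_px = (pts_nm + tube.radius_nm * normal) / px
    return MembranePath.from_pixel_points(offset_px, px,
                                          source=f"phantom-surface-{tube_index}")


def _draw_gap_intervals(length_nm: float, gap_fraction: float, min_len_nm: float,
                        rng) -> list:
    """Non-overlapping intervals totaling ~gap_fraction of the path length.

    Lengths are uniform in [min, 3*min]; the final interval is sized to close
    out the target exactly when it can, so the total matches gap_fraction *
    length within one minimum-gap quantum; intervals are placed by rejection
    sampling without overlap.
    """
    target = gap_fraction * length_nm
    if target == 0:
        return []
    if min_len_nm > length_nm:
        raise ParameterError("min gap length exceeds the path length")
    intervals: list = []
    total = 0.0
    tries = 0
    while total < target:
        if tries > 10000:
            raise ParameterError("cannot place the requested gap fraction without overlap")
        tries += 1
        remaining = target - total
        if min_len_nm <= remaining <= 3 * min_len_nm:
            ln = remaining
        elif remaining < min_len_nm:
            ln = min_len_nm
        else:
            ln = rng.uniform(min_len_nm, 3 * min_len_nm)
        s0 = rng.uniform(0, length_nm - ln)
        if any(s0 < e + min_len_nm / 2 and s0 + ln > s - min_len_nm / 2
               for s, e in intervals):
            continue
        intervals.append((s0, s0 + ln))
        total += ln
    return sorted(intervals)


def insert_gaps(phantom: PhantomVolume, gap_fraction: float,
                min_gap_len_nm: float | None = None, seed: int = 0) -> PhantomVolume:
    """Remove shell voxels along random arclength intervals of each truth path."""
    if not 0 <= gap_fraction < 1:
        raise ParameterError(f"gap fraction must be in [0, 1), got {gap_fraction}")
    min_len = min_gap_len_nm if min_gap_len_nm is not None else phantom.spec.min_gap_len_nm
    out = copy.deepcopy(phantom)
    if gap_fraction == 0:
        return out
    rng = np.random.default_rng(seed)
    membrane = out.images.data[out.images.channel_names.index("membrane")]
    for i, path in enumerate(out.paths_truth):
        gaps = _draw_gap_intervals(path.length_nm, gap_fraction, min_len, rng)
        out.gaps_truth[i] = gaps
        if not gaps:
            continue
        vox, arc = out.voxel_arclength[i]
        in_gap = np.zeros(len(arc), bool)
        for s, e in gaps:
            in_gap |= (arc >= s) & (arc < e)
        idx = tuple(v[in_gap] for v in vox)
        membrane[idx] = 0.0
        out.shell_mask[idx] = False
    return out


def _noisy(signal: np.ndarray, spec: PhantomSpec, rng) -> np.ndarray:
    img = rng.poisson(signal + spec.background_level).astype(float)
    if spec.gauss_read_noise > 0:
        img += rng.normal(0, spec.gauss_read_noise, img.shape)
    return np.clip(img, 0, None)


def render_image(phantom: PhantomVolume, n_realizations: int = 1, seed: int = 0):
    """PSF-blur the geometry, scale to photons, and sample Poisson+read noise.

    With ``n_realizations=2`` the same blurred signal receives two
    independent noise draws (the acquisition protocol behind FRC analysis).
    Returns an ImageStack, or a list of them for multiple realizations.
    """
    if n_realizations not in (1, 2):
        raise ParameterError("n_realizations must be 1 or 2")
    spec = phantom.spec
    sig_px = spec.psf_sigma_px
    blurred = [ndimage.gaussian_filter(phantom.images.data[c], sig_px)
               for c in range(phantom.images.n_channels)]
    # photon_scale is the expected peak photon count of the rendered membrane
    peak = blurred[0].max()
    signal = np.stack([b / peak * spec.photon_scale if peak > 0 else b
                       for b in blurred])

    rng = np.random.default_rng(seed)
    stacks = []
    for _ in range(n_realizations):
        stacks.append(ImageStack(_noisy(signal, spec, rng),
                                 pixel_size_nm=phantom.images.pixel_size_nm,
                                 expansion_factor=spec.expansion_factor,
                                 channel_names=phantom.images.channel_names))
    return stacks[0] if n_realizations == 1 else stacks


def _best_plane(geom: np.ndarray) -> int:
    return int(np.argmax(geom.sum(axis=(1, 2))))


def make_fluctuation_series(phantom: PhantomVolume, n_frames: int = 20,
                            blink_on_prob: float = 0.5, seed: int = 0,
                            z_plane: int | None = None) -> ImageStack:
    """Render a (t, y, x) blinking-frame series from one plane of the geometry.

    Every shell voxel carries an independent two-state Bernoulli time course;
    frames are PSF-blurred and noise-sampled like single acquisitions.
    """
    if n_frames < 2:
        raise ParameterError(f"need n_frames >= 2, got {n_frames}")
    if not 0 < blink_on_prob <= 1:
        raise ParameterError(f"blink_on_prob must be in (0, 1], got {blink_on_prob}")
    spec = phantom.spec
    geom3 = phantom.membrane()
    z = z_plane if z_plane is not None else _best_plane(geom3)
    geom = geom3[z]
    emit = np.nonzero(geom)
    vals = geom[emit]
    sig_lat = spec.psf_sigma_px[1:]
    peak = ndimage.gaussian_filter(geom, sig_lat).max() if vals.size else 1.0

    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        on = rng.random(len(vals)) < blink_on_prob
        g = np.zeros_like(geom)
        g[emit] = vals * on
        signal = ndimage.gaussian_filter(g, sig_lat) / peak * spec.photon_scale
        frames.append(_noisy(signal, spec, rng))
    return ImageStack(np.stack(frames), pixel_size_nm=phantom.images.pixel_size_nm,
                      expansion_factor=spec.expansion_factor,
                      channel_names=("membrane",), axes="ctyx")


def make_distorted_pair(phantom: PhantomVolume, expansion_factor: float | None = None,
                        deformation_amp_nm: float = 50.0,
                        deformation_scale_px: float = 32.0, seed: int = 0,
                        n_landmarks: int = 6, n_texture_blobs: int = 60):
    """Build a matched pre/post-expansion 2D image pair with known deformation.

    The "pre" image is a PSF-blurred plane of the geometry plus bright
    landmark puncta and a dense field of dim blobs emulating the
    mitochondria-filled cells used for real distortion measurements (sparse
    images leave non-rigid registration unconstrained); the "post" image is
    the pre geometry scaled by the expansion factor then warped by a smooth
    random displacement field of RMS magnitude ``deformation_amp_nm``
    (biological nm, measured in the pre frame).  Returns
    (pre, post, landmark truth, deformation truth).
    """
    spec = phantom.spec
    factor = float(expansion_factor if expansion_factor is not None
                   else spec.expansion_factor)
    if factor < 1:
        raise ParameterError(f"expansion factor must be >= 1, got {factor}")
    if deformation_amp_nm < 0:
        raise ParameterError("deformation amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    bio_px = float(spec.bio_pixel_nm[1])

    geom = phantom.membrane()[_best_plane(phantom.membrane())]
    plane = ndimage.gaussian_filter(geom, spec.psf_sigma_px[1:])
    if plane.max() > 0:
        plane = plane / plane.max()
    h, w = plane.shape
    lm = np.column_stack([rng.uniform(0.15 * h, 0.85 * h, n_landmarks),
                          rng.uniform(0.15 * w, 0.85 * w, n_landmarks)])
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_texture_blobs):
        by, bx = rng.uniform(0, h), rng.uniform(0, w)
        s = rng.uniform(1.5, 4.0)
        plane = plane + rng.uniform(0.3, 0.9) * np.exp(
            -((yy - by) ** 2 + (xx - bx) ** 2) / (2 * s * s))
    for (ly, lx) in lm:
        plane = plane + 1.5 * np.exp(-((yy - ly) ** 2 + (xx - lx) ** 2) / (2 * 2.0 ** 2))

    # smooth random displacement field in pre-frame pixels
    if deformation_amp_nm > 0:
        u = ndimage.gaussian_filter(rng.standard_normal((2, h, w)),
                                    (0, deformation_scale_px, deformation_scale_px))
        rms = np.sqrt(np.mean(u[0] ** 2 + u[1] ** 2))
        u *= (deformation_amp_nm / bio_px) / rms
    else:
        u = np.zeros((2, h, w))

    hp, wp = int(round(h * factor)), int(round(w * factor))
    YY, XX = np.mgrid[0:hp, 0:wp]
    ys, xs = YY / factor, XX / factor  # post pixel -> pre frame
    uy = ndimage.map_coordinates(u[0], [ys, xs], order=1, mode="nearest")
    ux = ndimage.map_coordinates(u[1], [ys, xs], order=1, mode="nearest")
    post = ndimage.map_coordinates(plane, [ys - uy, xs - ux], order=1, mode="nearest")

    u_at = np.stack([ndimage.map_coordinates(u[k], lm.T, order=1) for k in range(2)],
                    axis=1)
    landmarks = LandmarkSet(pre=np.column_stack([np.zeros(n_landmarks), lm]),
                            post=np.column_stack([np.zeros(n_landmarks),
                                                  factor * (lm + u_at)]))
    pre_stack = ImageStack(plane, pixel_size_nm=(bio_px, bio_px, bio_px),
                           expansion_factor=1.0, channel_names=("membrane",))
    post_stack = ImageStack(post, pixel_size_nm=(bio_px, bio_px, bio_px),
                            expansion_factor=factor, channel_names=("membrane",))
    truth = DeformationField(dy_nm=u[0] * bio_px, dx_nm=u[1] * bio_px,
                             bio_pixel_nm=bio_px)
    return pre_stack, post_stack, landmarks, truth
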