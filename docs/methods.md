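# Methods

This note documents the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic phantoms do and do not emulate, and
the numerical conventions a user should know before trusting a number.

## Units and conventions

All arrays are indexed `(z, y, x)` (or `(t, y, x)` for frame series), 0-based
and pixel-centered. `pixel_size_nm` always refers to the expanded sample;
**biological units** are physical lengths divided by the linear expansion
factor, and every reported length (resolution, gap length, diameter, RMS
error) is biological. A 108.3 nm physical pixel at 4x expansion is therefore
a 27.075 nm biological pixel, and the ~500 nm axial extent of a confocal PSF
becomes ~125 nm.

Metadata precedence when reading stacks: explicit overrides beat OME-TIFF
metadata, which beats nothing (a file without pixel sizes and without an
override is an error, never a silent default).

## Resolution: blockwise Fourier ring correlation

Two acquisitions of the same field with independent noise are Fourier
transformed and correlated over integer-width frequency rings:

    FRC(r) = Re sum_r F_a conj(F_b) / sqrt(sum_r |F_a|^2 sum_r |F_b|^2)

The resolution is `1/f*` at the curve's first downward crossing of the fixed
**1/7 threshold** (the convention of the widely used FRC plugin ecosystem),
with linear interpolation between rings. A curve that never crosses is
reported at the 2-pixel Nyquist bound and flagged `"limit"` rather than
invented. A 2D Hann window is applied by default to suppress edge leakage;
tests that compare against the brute-force ring-summation oracle disable it.

Blockwise mode tiles the pair into `block_size_px` tiles (default 128),
scores tiles whose fraction of above-background pixels exceeds
`min_block_content` (default 0.2; background is the mean + 2 SD of the
lowest-decile pixels), and reports the per-block map plus the **minimum**
(finest) block resolution as the headline value. "Best block" could also be
read as best correlation; the minimum-resolution rule is used and recorded in
the output metadata.

For fluctuation data, a 40-frame series is split into odd and even 20-frame
halves; each half is averaged (or SACD-reconstructed) and the halves serve as
the independent pair.

## Expansion factor and distortion

The expansion factor is the mean of post/pre ratios over **all C(n,2)
inter-landmark distances** (physical units), with SD and a normal-theory 95%
CI. Coincident pre-expansion landmarks are an error, not a skipped pair.

Distortion is quantified in 2D planes. The post image is first brought into
pre coordinates by downscaling (1/factor) — never upscaling the pre image,
which would invent detail. Rigid alignment is a grid search over rotation
(default ±10° in 0.25° steps) with subpixel translation by phase correlation,
scored by normalized cross-correlation; a best score below 0.2 is a
registration failure. The non-rigid residual is estimated with TV-L1
variational optical flow on lightly band-limited images (1 px Gaussian on
both inputs, compensating the bandwidth asymmetry left by the post image's
anti-alias filter). The field is zeroed outside the pre image's content mask.

The RMS length-measurement-error curve samples, for each measurement length
L (default 10 log-spaced bins from 1 µm to half the field extent, 1000 pairs
per bin, seeded), random point pairs at separation L inside the mask and
reports the RMS of | |(p2+u2)−(p1+u1)| − L |. Rigid components cancel
exactly in this statistic; a uniform 1% misscaling gives rms(L) = 0.01·L,
which the tests verify against the closed form.

Note the rigid/non-rigid decomposition is not unique: a random smooth field
has a net translation/rotation component that rigid alignment absorbs.
Truth-field recovery is therefore validated on pre-aligned pairs, while the
full pipeline is validated on the rigid-invariant RMS curve.

## Membrane continuity and morphometry

Intensity is sampled along a traced path by trilinear interpolation at
uniform arclength steps (default half the lateral biological pixel). The
threshold is `mean − k_sd · SD` with mean and SD taken **along the same
path** (not the whole image), `k_sd = 2`. A gap is a maximal sub-threshold
run whose extent — first to last sub-threshold sample plus one step — exceeds
`min_gap_len_nm` (default 60 nm, the measured image resolution; callers
should pass their own FRC result). Runs separated by a single above-threshold
sample are not merged; a `closing_nm` parameter exists but defaults to 0.
Percent continuity is length-weighted: 100·(1 − total gap length / path
length), reported with the raw gap count.

Transverse profiles average an oriented box down its long axis (bilinear
sampling at quarter-pixel steps) and normalize to peak = 1. The diameter is
the distance between the two wall peaks, each refined by a 3-point parabolic
fit; a single-peaked profile raises an unresolved-walls error instead of
returning a number, because a structure thinner than the resolution has no
measurable wall separation.

## Signal-to-background

Background is the pixel-weighted grand mean over one or more empty-gel
reference images (matched acquisition settings are the caller's contract).
The profile is the per-plane mean over **all** pixels of each XY plane
divided by that scalar — no tissue mask, matching how such ratios are
reported for uniformly labeled tissue; a mask flag exists but defaults off.

## Segmentation and tracing agreement

The Rand score is computed from label-contingency sums (never enumerating
pairs): with n_ij the joint label counts, agreeing pairs are those co-labeled
in both volumes plus those separated in both. By default only voxels
foreground in the reference ("ground truth") volume are evaluated. The plain
pair-counting Rand index is the headline value; the connectomics
adapted-Rand F-score `2·Σn_ij² / (Σa_i² + Σb_j²)` is available as a variant
and both can be reported, since published Rand values do not always state
which was used. Both are label-permutation invariant; the plain score is
symmetric when the foreground restriction is off.

Tracings are compared by rasterizing each centerline annotation into a tube
of the annotation brush radius (one label per trace, later traces win on
overlap, with the multiply-claimed fraction reported) and Rand-scoring the
tubes.

Colocalization is |reference ∧ probe⁺| / |reference| with the probe channel
thresholded by Otsu (default), a percentile, or a fixed value; the method is
recorded in the output.

## SACD fluctuation reconstruction

Pipeline, per the published default hyper-parameters (1st = 10, fourier = 2,
2nd = 10, order = 2): each frame is Richardson–Lucy deconvolved (10
iterations, Gaussian PSF with sigma = 0.21·λ/NA at the native grid), Fourier
upsampled 2x (zero padding with symmetric Nyquist-bin splitting, so real
images stay real and the mean is preserved), then the per-pixel **lag-0
second-order central cumulant** (temporal variance) is taken, clipped at 0,
and deconvolved again with the PSF mapped to the upsampled grid and narrowed
by 1/sqrt(order). Design choices where the reference tool is unspecific:
variance (lag 0) rather than lag-1 autocorrelation, which is ill-conditioned
for 20-frame series; deconvolution before upsampling to bound cost; CLAHE is
excluded from the quantitative path (display only). Richardson–Lucy is
initialized at the input image (so 0 iterations is the identity) and uses
edge-replicated padding so flat regions are true fixed points.

## Synthetic phantoms: the stated world

Geometry: tubes defined by centerline control points (cubic-spline densified)
with shells rendered by distance to the centerline, |d − r| < thickness/2,
antialiased linearly over one voxel; a myelinated flag makes the shell 3x
thicker and 2x brighter; an optional lumen fill channel emulates a cytosolic
fill label. Default volume 64×256×256 at 25 nm biological pixels, expansion
factor 4.

Optics and noise: separable anisotropic Gaussian PSF with physical FWHM
250 nm lateral / 500 nm axial (the scales of a high-NA confocal), Poisson
photon noise at `photon_scale` expected peak photons (default 200 over a
background of 5 — a ~40-fold signal-to-background, the regime reported for
well-labeled tissue), plus Gaussian read noise (SD 2). Rendering is
bit-reproducible from (spec, seed).

Gaps: non-overlapping arclength intervals with lengths uniform in
[min, 3·min] (default min 200 nm, at least 3x the 62.5 nm biological PSF
FWHM so an inserted gap is optically resolvable); the final interval is sized
to close out the requested fraction exactly, so the total matches g·L within
one quantum. Continuity experiments trace the **membrane surface** (the
centerline offset radially by the tube radius), since the label lives on the
shell, not the lumen axis.

Distorted pairs: the post image is the pre plane scaled by the expansion
factor and warped by a band-limited random displacement field of prescribed
RMS amplitude (default 50 nm biological, correlation length 32 px); landmark
truth is carried by bright puncta. The pre plane also receives a dense field
of dim blobs emulating the organelle-filled cells used for real distortion
measurements — sparse scenes leave non-rigid registration unconstrained
between structures.

Blinking: every shell voxel gets an independent two-state Bernoulli time
course (default on-probability 0.5, 20 frames, matching short fluctuation
acquisitions); series are rendered from the 2D plane of maximal shell
content, as fluctuation imaging is per-plane.

What the phantoms do **not** emulate: spatially varying neuropil background
(background is constant), optical aberrations beyond a Gaussian PSF,
scattering, bleaching, or correlated emitter kinetics. A green test therefore
establishes that an algorithm recovers known truth under idealized optics and
noise — not that a specific biological number is correct on real tissue,
where those headline values depend on the deposited data and manual
annotations.

## Numerical details worth knowing

- FRC rings are one frequency sample wide, from ring 1 to Nyquist;
  correlations are clipped to [−1, 1]; an all-zero input is a degenerate
  error, and a curve already below threshold at ring 1 is a no-signal error.
- Sparse low-frequency rings contain few pixels, so pure-noise FRC values
  fluctuate as 1/sqrt(n_ring); statistical independence checks weight rings
  by pixel count.
- Gap detection with SD = 0 (constant profile) returns an empty gap set
  flagged `degenerate-sd` rather than dividing by zero.
- Reports are written as JSON (scalars, field order fixed by the dataclass)
  plus CSV (equal-length array fields), so outputs diff cleanly run to run.

## Known limitations

- Distortion analysis is 2D per plane; no 3D deformation fields or Fourier
  shell correlation.
- The non-rigid stage is dense optical flow rather than a parametric
  B-spline free-form deformation; the recovered field is reliable where the
  image has structure and is masked elsewhere.
- Cumulant orders above 2 are an explicit extension point, not implemented.
- ImageJ ROI import covers straight-line, polyline, and freeline types with
  integer coordinates; the JSON polyline schema is the canonical format.
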