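# memquant

Quantification pipeline for dense membrane-label expansion microscopy.

Expansion microscopy physically magnifies fixed tissue ~4x per linear
dimension inside a swellable hydrogel, so that a standard confocal microscope
resolves membrane ultrastructure — axons, myelin sheaths, cilia — at an
effective resolution of tens of nanometres. Validating such a protocol is an
image-analysis problem: How fine is the effective resolution? How isotropic
is the expansion? How continuous is the membrane labeling along a single
membrane? Can one trace and segment neuronal processes from the label alone?
`memquant` implements these quantifications as a tested, reusable library
and CLI, together with a synthetic membrane-phantom generator that carries
complete ground truth, so every stage is verifiable without microscopy data.

## What it computes

| Stage | Statistic |
|---|---|
| `frc` | Blockwise Fourier ring correlation between two independent acquisitions; resolution = 1/f* at the first crossing of the 1/7 threshold, in biological nm (physical / expansion factor) |
| `distortion` | Expansion factor as the mean post/pre ratio over all C(n,2) inter-landmark distances; non-rigid registration of pre/post pairs and the RMS length-measurement-error curve rms(L) |
| `membrane` | Percent continuity: fraction of a traced membrane outside gaps, a gap being a run more than 2 SD below the path mean and longer than the resolution (60 nm); transverse profiles and wall-to-wall diameters |
| `sbr` | Per-plane signal-to-background ratio against an empty-gel background |
| `segmentation` | Pair-counting Rand score between label volumes (plain and adapted variants), trace-to-tube rasterization, colocalization fractions |
| `sacd` | Fluctuation super-resolution: per-frame Richardson–Lucy, 2x Fourier upsampling, per-pixel temporal variance (order-2 cumulant), second deconvolution with the PSF narrowed by 1/sqrt(2) |
| `phantom` | Membrane-shell phantoms (tubes of 100–1500 nm diameter, thin antialiased shells, optional lumen fill), anisotropic Gaussian PSF, Poisson + read noise, inserted gaps of known fraction, smooth deformation fields, blinking frame series — all seeded and bit-reproducible |

## Worked example

```python
import numpy as np
from memquant import phantom, membrane, frc

# a 10 um synthetic cilium: 150 nm-radius membrane shell, 5% of its length
# removed as labeling gaps, imaged twice with independent noise
tube = phantom.TubeSpec(np.array([[6, 16, 2], [6, 16, 210], [6, 16, 417]]),
                        radius_nm=150, shell_thickness_nm=40)
spec = phantom.PhantomSpec(shape=(12, 32, 420), tubes=[tube],
                           fill_channel=False, seed=0)
vol = phantom.insert_gaps(phantom.make_tube_phantom(spec), 0.05, seed=1)
img_a, img_b = phantom.render_image(vol, n_realizations=2, seed=2)

# effective resolution from the independent pair (biological nm)
bio_px = float(img_a.bio_pixel_size_nm[2])
curve = frc.frc_curve(img_a.plane(6)[0:32, 98:130],
                      img_b.plane(6)[0:32, 98:130], bio_px)
res = frc.frc_resolution(curve, bio_px)
print(f"FRC resolution: {res.resolution_nm:.1f} nm ({res.flag})")

# continuity of the membrane label along the traced shell
path = phantom.surface_path(vol, 0)
prof = membrane.sample_path_intensity(img_a, path, channel="membrane")
result = membrane.percent_continuity(prof, membrane.detect_gaps(prof))
truth = 100 * (1 - sum(e - s for s, e in vol.gaps_truth[0]) / path.length_nm)
print(f"continuity: {result.percent_continuity:.1f}% measured "
      f"({result.n_gaps} gaps), {truth:.1f}% ground truth")
```

prints

```
FRC resolution: 82.7 nm (ok)
continuity: 94.8% measured (1 gaps), 95.0% ground truth
```

The resolution sits above the 50 nm Nyquist bound of the 25 nm biological
pixels, as it must for a noisy pair, and the measured continuity recovers the
known inserted gap fraction to within a fraction of a percentage point.

## Command line

```sh
memquant --seed 0 simulate --out phantom --gap-fraction 0.03
memquant frc --a a.ome.tif --b b.ome.tif --expansion-factor 4 --out frc_out
memquant continuity --image img.ome.tif --channel membrane \
         --paths traces.json --ksd 2 --min-gap 60 --out cont_out
memquant expansion --landmarks landmarks.csv --out exp_out
memquant distort --pre pre.tif --post post.tif --factor 4 \
         --pixel-size-nm 25 --out dist_out
memquant sbr --volume vol.ome.tif --background bg1.tif --out sbr_out
memquant randscore --a seg_a.tif --b seg_b.tif --out rand_out
memquant coloc --ref mask.tif --probe img.tif --out coloc_out
memquant sacd --series frames.ome.tif --pixel-size-nm 108.3 --out sacd_out
```

All commands accept `--config cfg.yaml` (see `memquant.config.AnalysisConfig`)
and a global `--seed`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates phantoms from scratch and runs every pipeline stage on them —
blockwise FRC on an independent noise pair, continuity on a gapped cilium,
expansion-factor and distortion-curve estimation on a deformed pre/post pair,
Rand scoring of jittered traces, and a SACD reconstruction — printing a
summary of the measured quantities.

See `docs/methods.md` for the models, defaults, and known limitations.
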