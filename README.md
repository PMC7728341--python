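# voldvc

Subset-based **digital volume correlation (DVC)** for clinical-resolution
volumetric images, with a full **zero-strain uncertainty-quantification**
workflow.

DVC tracks the grayscale texture between two 3-D image volumes — e.g.
repeated MRI scans of a bone — to measure internal displacement and strain
fields non-invasively. At clinical resolution (~0.5 mm voxels) the errors
of such a measurement are of the same order as physiological bone strains
(hundreds to thousands of microstrain), so quantifying them is not
optional: `voldvc` is built around the *zero-strain test*, in which two
scans of an unloaded object are correlated and every nonzero displacement
or strain that comes out is, by construction, measurement error.

Intended users: researchers in musculoskeletal biomechanics and volumetric
image analysis who need a transparent, scriptable DVC chain with synthetic
ground-truth phantoms for validation.

## What it computes

The volume is tiled with cubic N-voxel subsets (50 % overlap, windows with
at least the MFVP fraction of in-mask voxels). Pattern match at integer
shift (dx, dy, dz) is scored by the normalised correlation coefficient

    C_norm(dx,dy,dz) = Σ A*·B* / sqrt(Σ A*² · Σ B*²),

with A\*, B\* the mean-subtracted window intensities — invariant to
illumination changes between scans. Three search engines locate the peak:

| approach | strategy |
|----------|----------|
| `dc`     | exhaustive C_norm over a ±r integer lattice |
| `fft`    | circular FFT cross-correlation of the windows, peak unwrapped to [-N/2, N/2) |
| `fft_dc` | FFT peak as predictor, then a local ±2 DC refinement (recommended) |

A three-point Gaussian fit per axis refines the peak to sub-voxel
precision. A coarse-to-fine multi-pass scheme (64-56-48-40, 3 iterations
per size) is available. Strain follows by centred finite differences on
the subset grid,

    ε_ij = ½ (ΔV_i/Δj + ΔV_j/Δi),   Δ = 2 · stride · voxel size,

and zero-strain runs are summarised by the per-axis random displacement
error (SD of components, µm), the strain accuracy **MAER** (mean over
points of the six-component mean absolute strain, µε), the precision
**SDER** (SD of that quantity), per-component statistics, and power-law
fits `a · SS^b` of error against subset size SS.

Rigid inter-scan motion is removed first by a six-parameter intensity-based
registration (Nelder-Mead over 3 translations + 3 rotations with an
integer-voxel pre-search).

Everything is validated against analytic phantoms: Gaussian-blob speckle
evaluable at any continuous coordinate, so prescribed rigid/affine/
sinusoidal deformations are applied *exactly* and recovery errors are
attributable to the correlation machinery alone.

## Worked example

Generate a zero-strain phantom pair at SNR 306.2 with a small inter-scan
offset, then run the full workflow:

```bash
voldvc synth --out demo --shape 96,96,96 --snr 306.2 \
       --offset 1.3,-0.6,0.4 --mask-kind full --seed 7
voldvc zero-strain --reference demo/reference.nii.gz \
       --repeat demo/repeat.nii.gz --mask demo/mask.nii.gz \
       --subset 32 --approach fft_dc --out-dir demo/run
```

The same thing from Python:

```python
import voldvc as vd

ref, rep, mask, truth = vd.synth_pair(
    shape=(96, 96, 96), snr=306.2, offset_vox=(1.3, -0.6, 0.4),
    mask_kind="full", seed=7,
)
report = vd.zero_strain_report(
    ref, rep, mask, vd.DvcSettings(approach="fft_dc", subset_size=32)
)
print(report.to_json())
```

which prints (abridged):

```
{
  "random_displacement_error_um": {"x": 2.94, "y": 4.66, "z": 3.22},
  "maer_ue": 286.7,
  "sder_ue": 105.4,
  "mean_cnorm": 0.99928,
  "n_subsets": 8,
  "n_vectors": 64
}
```

Read this as: after rigid correction of the 1.3-voxel inter-scan offset,
the 32-voxel-subset FFT+DC pipeline mis-measures displacement by ~3–5 µm
(SD per axis, at 500 µm voxels — i.e. ~1/130 voxel) and reports a mean
spurious strain of ~287 µε with ~105 µε spread over the 8 interior grid
points, on a pair whose true strain is exactly zero. Those numbers *are*
the measurement uncertainty of this configuration at that noise level; the
slightly elevated y components trace back to the trilinear resampling of
the corrected scan along the largest offset axis.

Sweeps over subset size with power-law trend fits:

```bash
voldvc sweep --config sweep.json   # subset_sizes: [16, 24, 32, 40, 48, 56]
```

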