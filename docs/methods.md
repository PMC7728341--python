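# Methods

`voldvc` measures internal displacement and strain between two 3-D grayscale
volumes by local (subset-based) digital volume correlation, and quantifies
the uncertainty of the whole chain with zero-strain tests. This note records
the models, conventions, numerical choices and their rationale.

## Measurement model

The volume pair is a *reference* A and a *deformed/repeat* B on the same
isotropic grid (voxel size `vs` mm). A binary region-of-interest mask
restricts the analysis (e.g. to one bone). The measurement volume is tiled
with cubic N-voxel subsets; consecutive window starts differ by
`stride = round(N (1 - overlap))` (default overlap 0.5, so stride N/2). A
window is *active* when its in-mask voxel fraction reaches the MFVP
threshold (default 0.5, inclusive comparison, so a window exactly at the
threshold still produces a vector). Each active subset yields one
displacement vector.

### Match quality

Pattern match at an integer shift (dx, dy, dz) is scored by the normalised
correlation coefficient

    C_norm = sum(A* B*) / sqrt(sum(A*^2) sum(B*^2)),

with A*, B* the mean-subtracted window intensities. C_norm is the cosine
between the centred windows: 1 for a perfect match, invariant under
`b -> alpha b + beta` (alpha > 0), which removes global illumination /
gain differences between scans. Masked voxels are excluded from every sum
and the voxel count replaces N^3 in the means — the minimal extension of
the fully-valid formula to windows that straddle the mask edge.

### Search strategies

* **DC** — exhaustive evaluation over a `[-r, r]^3` integer lattice
  (default r = N/4). Shifts whose window leaves the volume are skipped.
  A peak on the lattice boundary is flagged `out_of_range`, not accepted:
  boundary maxima are unreliable.
* **FFT** — the mean-subtracted windows are circularly cross-correlated via
  FFT, the circular peak is unwrapped to `[-N/2, N/2)` per axis. This gives
  every possible shift at once and is cheap for large motions, but the
  non-periodic window content contaminates the peak by roughly the
  non-overlapping fraction (~|d|/N per axis); with coarse texture this is
  its dominant error source.
* **FFT+DC** — the FFT integer peak becomes a predictor; the deformed
  window is re-extracted at that offset and a small DC search
  (±refine_range, default 2) around it gives the final refined vector.
  This combines large-motion capture with DC's local accuracy.

Ties at the correlation maximum resolve deterministically: smallest
Euclidean norm of the total shift, then lexicographic order.

### Sub-voxel refinement

A three-point Gaussian fit per axis on the 3x3x3 neighbourhood of the
integer peak:

    delta = (ln c- - ln c+) / (2 ln c- - 4 ln c0 + 2 ln c+),

the standard PIV/DVC estimator; it is exact when the local correlation
profile is Gaussian, which the Gaussian-blob phantom makes literally true.
Values are shifted positive before taking logs; if that fails the parabolic
three-point fit is used, and any non-finite intermediate or |delta| >= 1
falls back to 0. Axes whose +-1 neighbour lies outside the valid search
lattice (windows at the volume border) contribute no refinement — these are
exactly the edge vectors whose strain is least reliable. When the
integer-peak C_norm is numerically 1 (>= 1 - 1e-9) the windows are exactly
aligned (Cauchy-Schwarz equality holds only for identical centred
patterns), so the fractional part is 0 by definition; this makes the
zero-strain fixed point of the whole pipeline exact rather than merely
small.

### Multi-pass scheme

A coarse-to-fine predictor-corrector adapted from particle image
velocimetry: the field measured at one subset size is interpolated
(trilinearly; nearest-neighbour outside the previous grid hull) onto the
next, finer grid and rounded to integer voxels to pre-shift each deformed
window. The default schedule is sizes 64-56-48-40 with 3 correlation passes
per size ("iterations" is read as per-size repeats; each repeat updates the
predictors). Vectors with non-ok status contribute a zero predictor.

## Rigid pre-registration

Residual rigid motion between repeated scans is estimated by minimising the
intensity distance over 3 translations + 3 rotations (intrinsic x-y-z about
the volume centre; the convention is arbitrary but fixed and serialized
with every transform). The optimizer is Nelder-Mead, initialized at the
identity after a coarse integer-voxel grid search over translations
(±4 voxels, step 2; integer shifts are applied exactly by slicing, no
interpolation). Resampling is trilinear; identity transforms and exact
integer-voxel translations bypass interpolation entirely.

One deliberate deviation from the naive objective: out-of-field voxels
(zero-filled by resampling) are excluded from the sum and the summed square
is rescaled to the full ROI voxel count. With a nonzero background
intensity the zero-filled border otherwise dominates the distance and the
optimizer cannot move at all. The plain sqrt-of-summed-squares distance is
still available as `euclidean_distance`.

Convergence: relative objective change < 1e-6 or 500 iterations;
non-convergence warns and returns the best transform, flagged.

After correction, the workflow restricts the ROI to the resampling's valid
region eroded by the correlation search margin. Border voxels of the
corrected scan are zero-filled fabrications; a correlation shift that reads
them (or a sub-voxel neighbour beside them) acquires a bias of up to a few
tenths of a voxel, so those reads are excluded before any window is formed.

## Strain

Six-component small-strain tensors by centred finite differences on the
subset grid:

    eps_ij = (dVi/dj + dVj/di) / 2,

with dV taken between the +1 and -1 grid neighbours. The denominator is the
*actual* physical span between those neighbours, `2 stride vs` (default).
The textbook "2 x subset length" convention equals this only for
non-overlapping subsets; at 50 % overlap it would double the span and halve
every strain, so it is provided only as the `spacing="subset"`
compatibility flag. Output is in microstrain (ue).

Boundary grid points get no strain (no one-sided differences — edge strains
are systematically the worst, and silently reporting them invites
misinterpretation), and any stencil touching a non-ok vector is invalid.

## Zero-strain uncertainty metrics

Two repeated scans of an unloaded object carry zero true strain; whatever
the pipeline reports is its error.

* Random displacement error: per-axis sample SD (ddof = 1) of the ok-subset
  displacement components, in um.
* MAER (accuracy): mean over valid strain points of the six-component mean
  absolute strain, ue.
* SDER (precision): SD of that per-point quantity about MAER, population
  convention (1/N) exactly as the definition prints; `population=False`
  switches to 1/(N-1).
* Per-component accuracy/precision: mean and sample SD of |eps_c| per
  component.
* Error-vs-subset-size trends: least squares on (log SS, log value) —
  a spreadsheet-style power-law trendline `a * SS^b` with R^2 computed on
  the log scale; a constant response is reported as b = 0, R^2 = 1.

Only ok vectors and valid strain points enter any statistic.

## Synthetic phantoms

The generator emulates the zero-strain study conditions without scan data:

* **Texture**: a sum of Gaussian blobs evaluated analytically at any
  continuous coordinate (truncated at 7 sigma, < 3e-11 of an amplitude).
  Deformed volumes are the model at pulled-back coordinates, so *no*
  resampling error enters: recovery errors are attributable to the
  correlation machinery alone. Defaults: blob sigma 1.0 mm, density
  0.004 blobs/mm^3 (~32 blobs in a 40-voxel subset at 0.5 mm voxels),
  amplitudes U(0.5, 1.5), background level 0.5. The background fixes how a
  nominal SNR (in-mask mean over noise SD) maps onto texture contrast; it
  is calibrated so that a repeated-scan pair at SNR 9.8 retains a window
  correlation of ~0.88 — degraded but trackable, the regime clinical
  T2-weighted scans show — while SNR 306.2 tracks nearly cleanly.
* **Deformations**: rigid (exact inverse), affine (exact inverse, exact
  strain (F + F^T)/2), and per-axis trigonometric displacement with the
  small-displacement pull-back x - u(x) (inversion error second order,
  negligible at the <= 2-voxel amplitudes used).
* **Noise**: additive zero-mean Gaussian, sigma = (mean in-mask intensity) /
  target SNR, independent seeds per scan (spawned from one acquisition
  seed). At SNR >= ~10 the Rician magnitude statistics of MRI are
  approximately Gaussian, so the simpler model suffices for ordering and
  trend studies. SNR is *measured* as mean in-mask intensity over
  out-of-mask SD — the standard single-image estimate; phantoms meant for
  SNR measurement confine blobs to an eroded ellipsoid so the background
  holds only noise.
* **Masks**: ellipsoids (a convex stand-in for a segmented bone) or the
  full volume.

What the phantoms do *not* emulate: anatomically realistic geometry and
intensity distributions, Rician noise at very low SNR, scanner drift,
motion artefacts, interpolation error from gridded (non-analytic) textures.
Passing recovery tests therefore demonstrates correctness of the
correlation/strain machinery under controlled conditions, not the error
magnitudes to expect on clinical scans.

### Texture fineness in recovery tests

Two deterministic recovery checks use a finer speckle (sigma 0.6 mm =
1.2 voxels, density 0.02/mm^3) instead of the default: exact integer-shift
recovery by the single-pass FFT approach, and uniform-strain recovery to
tight component tolerances. With 2-voxel blobs a window holds only ~150
independent speckles, so the FFT approach's circular contamination flips
~25 % of integer peaks by one voxel and component-mean residuals fluctuate
at the size of the tolerance — both are texture-sampling statistics, not
algorithm properties. The finer texture puts those tests in the regime they
are meant to probe. All noise-driven trend studies keep the default
texture.

### Problem sizes

Test and acceptance runs use phantoms between 48^3 and 160^3 voxels:
64–96^3 wherever a handful of subsets suffices, 112^3 for the subset-44
SNR comparison (4 grid points per axis), and 160^3 where fully-interior
strain stencils are needed (7 grid points per axis at subset 40/stride 20,
or >= 8 valid strain points at subset 56). "Interior" in recovery
statements means subsets whose full search lattice fits inside the volume —
border subsets lose sub-voxel refinement on the clipped side and are
reported but excluded from interior averages, mirroring the elevated edge
errors expected of any windowed method.

## Determinism and serialization

All generators are pure functions of their seeds; a run config (single seed
included) re-executes to byte-identical CSV/JSON artifacts. Floats are
written with 6 significant digits; manifests carry settings and versions
but no timestamps (stage wall-times go to the log only). Displacement CSVs
carry voxels and um columns (um = voxels * vs * 1000 exactly); strain CSVs
carry ue.

## Known limitations

* Translational subset shape functions only: no affine window deformation,
  so large strains (>~1 %) bias the correlation peak.
* The FFT approach's circular contamination is not apodized away (a window
  function is deliberately not applied by default; the FFT+DC combination
  is the recommended remedy, as its lower errors show).
* Strain at mask/volume edges is unreliable and deliberately not reported.
* Registration assumes the overlap of informative texture is large;
  symmetric multi-resolution schemes are out of scope beyond the coarse
  translation pre-search.
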