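# Methods

This note documents the models and numerical choices behind
`smallfov-mar`: a simulator and correction chain for metal artifact
reduction (MAR) in fan-beam CT when the scan field of view (FOV) is
smaller than the object, so that projections are truncated and metal
objects may sit outside the reconstructable region.

## Problem setting

Sinogram-inpainting MAR treats the metal trace — the sinogram samples
whose rays intersect metal — as missing data and interpolates across it.
This assumes the metal can be located in the reconstruction and that the
samples neighbouring the trace are trustworthy. Both assumptions fail in
small-FOV imaging: metal outside the FOV cannot be segmented from the
image, its trace corrupts the neighbourhood of the in-FOV traces, and the
measured projections carry exterior-object signal that no in-FOV prior can
match in level. The package implements a three-step correction:

1. **Truncation-corrected reconstruction.** Each truncated projection row
   is extended by `N_s` virtual samples per side: the innermost `N_ext`
   measured samples are mirrored about the detector edge and tapered by a
   cosine weighting (0–90°) so the extension decays smoothly to zero.
   The weighting over the full `2*N_ext + N_s` window is
   `cos((N_ext-N)/N_ext * pi/2)` for `N < N_ext`, 1 on the plateau, and the
   mirrored cosine on the upper branch. Weighted FBP of the extended
   sinogram yields a small-FOV image free of the bright truncation rim.
2. **Sinogram re-synthesis.** The small-FOV image is forward projected on
   a five-times oversampled detector and block-averaged to the native
   grid. This synthesized sinogram contains only in-FOV content: exterior
   metal trajectories are gone by construction.
3. **Inpainting MAR.** Metal is segmented from the Step-1 image by
   thresholding, forward projected to obtain the trace, and the
   *synthesized* sinogram is inpainted — either linearly along the
   detector direction (LMAR) or after normalization by the forward
   projection of a prior image in which bone is kept and soft tissue is
   flattened to the mean of its artifact-free part (NMAR). The final
   image is the FBP of the inpainted sinogram with the segmented metal
   pixels pasted back.

The "previous" baseline applies the same LMAR/NMAR directly to the
measured sinogram. Metal segmentation uses the truncation-corrected image
for both pipelines (segmenting on the raw truncated FBP would let the
bright rim masquerade as metal), and the baseline's final reconstruction
also applies the mirroring extension to the inpainted measured sinogram —
otherwise its score would be dominated by truncation artifact and the
comparison would no longer isolate residual *metal* artifact.

## System model

**Geometry.** Flat (equispaced) detector fan beam, full rotation, uniform
view spacing. Two presets: *conventional* (source–iso 700 mm, detector–iso
500 mm, 720 views, 1024 cells of 0.388 mm, 512x512 image at 0.7 mm) and
*dental* (500/200 mm, 720 views, 512 cells of 0.388 mm, 512x512 at
0.28 mm), plus `*_fast` variants with half the views/cells and half the
image resolution for quick experiments. The detector-limited FOV
`2*SID*sin(atan(W/2/SDD))` is ~228.7 mm for the conventional preset
(smaller than its 358.4 mm reconstruction extent) and ~140.4 mm for the
dental one (essentially its full extent); the package treats this
detector-limited circle as the "small FOV" for masking, reference
construction and the disk experiment.

**Projector.** Ray-driven line integrals: each source-to-cell ray is
clipped to the image square and sampled every half pixel with bilinear
interpolation. The adjoint used for testing is the exact matrix transpose
(bilinear scatter over the same samples), so `<Ax,y> = <x,A'y>` holds to
rounding. Chord-length accuracy on analytic disks is ~1% away from
grazing incidence.

**FBP.** Detector coordinates are rebinned to a virtual detector through
the iso-center, cosine weighted, ramp filtered (band-limited Ram-Lak
kernel, zero-padded FFT to at least twice the row length, halved for the
double coverage of a 2-pi fan scan) with optional Hann apodization
(default for final images), and backprojected pixel-driven with the
inverse-square distance weight. Self-consistency (FBP of FP) on a
band-limited phantom at the conventional preset is ~0.1% relative RMSE
inside 90% of the FOV.

**Polychromatic measurements.** Transmitted intensity is
`I = I0 * sum_E Omega(E) exp(-mu_w(E) d_w - mu_b(E) d_b - mu_m(E) d_m)`
with per-material path lengths from the projector, counts are Poisson
(`y ~ Poisson(I + r)`, `r` = 0 by default), and the log projection is
`p = -ln(y/I0)` with counts floored at 0.5 so photon-starved rays stay
finite. Defaults: 12 energy bins at 10–120 keV, `I0 = 1e5` photons per
cell per view. The spectrum is a generic 120 kVp tungsten-anode shape —
Kramers' law attenuated by 2.5 mm aluminium inherent filtration — since
no vendor spectrum table ships with the package; any two-column table can
be substituted. Attenuation coefficients for water, cortical bone and
gold come from a NIST-derived mass-attenuation table (10–120 keV) times
default densities 1.0 / 1.92 / 19.3 g/cm3. Mixed-material HU images are
split into water and bone components by the soft-threshold weighting
`w(x)` = 0 below 80 HU, 1 above 660 HU, linear in between, with
`x_b = w*x`, `x_w = (1-w)*x` (conserving `x` exactly).

**HU calibration.** HU conversion uses a configurable water attenuation;
standalone conversions default to water at 60 keV (0.02059 /mm). Pipeline
runs instead use a water-calibrated effective value,
`-ln(I(d)/I0)/d` for a 100 mm water slab under the simulation spectrum
(~0.0242 /mm), the analogue of a scanner's water calibration. Beam
hardening makes the effective attenuation thickness-dependent, so
reconstructed water still sits somewhat below 0 HU for thick objects;
thresholds are far enough apart (metal at 2000 HU vs metal values in the
tens of thousands) that this bias is immaterial for segmentation.

## Synthetic phantoms

The generator emits per-material density-fraction maps on the
reconstruction grid, rasterized with 4x4 sub-pixel coverage so analytic
line integrals are matched to well under 1%. Ellipse lists support
later-wins overlap semantics and an optional cosine-tapered soft edge for
band-limited objects.

The **disk phantom** emulates a bench experiment: a 250 mm water disk
with 32 bone cylinders of 5 mm diameter on a ring 5 mm inside its edge.
A requested number of cylinders inside and outside the small FOV are
replaced by metal. Design choices that the bench description leaves open:

- *Center offset (-15, 0) mm.* With the disk centered at iso, the
  cylinder ring (radius 120 mm) lies entirely outside the conventional
  small FOV (radius 114.3 mm) and "metals inside the FOV" would be
  impossible; the off-center placement (as in the bench photographs)
  puts ~7 slots fully inside and ~17 fully outside.
- *Eligibility margin.* A slot counts as inside (outside) only when the
  whole cylinder clears the FOV boundary by 3 mm, so no metal straddles
  the boundary and the inside/outside distinction is unambiguous.
- *Metal density fraction 0.12.* The nominal metal of the attenuation
  table is gold; solid 5 mm gold rods would be fully photon-starved at
  `I0 = 1e5` (true line integrals of ~40 against a log-transform ceiling
  of ~12), which buries segmentation and both MAR methods under extreme
  streaks. A density fraction of 0.12 gives the attenuation of a
  stainless-steel-like rod (steel attenuates roughly 12% as strongly as
  gold at diagnostic energies) — heavily attenuating and noisy in the
  trace, as in the bench scan, but not pathological.

The **reference image** removes all material outside the small FOV and
all metal, then simulates and reconstructs. It is the ground truth
against which NMSE/SSIM are scored.

What the generator does *not* emulate: anatomy (XCAT or clinical slices),
scatter, detector blur, bow-tie filtration, energy-integrating detector
weighting, and vendor spectra. Passing tests therefore demonstrate the
geometric/statistical mechanism of the correction, not clinical
performance.

## Evaluation

**NMSE** is `mean((f - f_ref)^2) / (mean(f) * mean(f_ref))` over a
rectangular ROI; **SSIM** is the single-window (global-statistics) form
`(2 mu_A mu_B + C1)(2 sigma_AB + C2) /
((mu_A^2 + mu_B^2 + C1)(sigma_A^2 + sigma_B^2 + C2))` with
`C1 = (0.01 L)^2`, `C2 = (0.03 L)^2`, `L` = the reference ROI's dynamic
range. A sliding-window SSIM is available as an explicitly non-default
mode. Metrics operate on linear-attenuation images, where means are
strictly positive.

For the disk experiment the scored ROI is a square of 1/sqrt(2) of the
FOV diameter centered midway between the FOV center and the inside-metal
cylinders — the streak-affected region a bench comparison marks — and the
(ground-truth) metal support, dilated by two pixels, is excluded from the
statistics: the reference deliberately contains no metal, so metal pixels
would otherwise dominate the error regardless of the artifact level. ROI
placement and exclusion are identical across pipelines and methods, so
all comparisons are paired.

## Numerical choices and degenerate cases

- *Truncation weighting indices.* The printed piecewise weighting is
  implemented literally; note that the rising branch attains
  `cos(pi/(2 N_ext))`, not exactly 1, at its last sample, so there is a
  one-sample discontinuity of order `1/N_ext^2` at the plateau. The
  extension applies the falling branch to the mirrored samples, which
  reaches zero exactly at offset `N_ext`; with the default `N_s = N_ext`
  the extension always ends at zero.
- *Truncation detection.* A side is extended only when its edge sample
  exceeds 1% of the row maximum; untruncated rows get zero padding, which
  makes the corrected reconstruction bit-compatible with plain FBP on
  untruncated data.
- *Synthesis filter.* The Step-1 reconstruction that is re-projected uses
  the same Hann apodization as final images. A sharp Ram-Lak here makes
  the resynthesis more faithful on noiseless data but injects
  reconstruction noise straight into the synthesized sinogram; at
  `I0 = 1e5` that costs more accuracy than the blur it avoids. The window
  is configurable.
- *NMAR division guards.* The prior sinogram is floored at `1e-6` of its
  maximum before division. Additionally, traced samples whose prior value
  is below 5% of the prior maximum — rays essentially outside the prior's
  support, e.g. grazing the FOV edge through air — are filled by plain
  linear interpolation, and such samples never serve as interpolation
  anchors: the normalized quotient carries no information there and
  diverges as the prior vanishes.
- *Fully traced rows* fall back to interpolation along the view
  direction with a warning.
- *Trace construction.* The metal mask is projected at 5x detector
  oversampling, rebinned, thresholded at `1e-6` of the maximum and
  dilated by one native bin to absorb discretization mismatch.
- *Prior construction.* Bone (>= 660 HU) is kept verbatim; soft tissue is
  flattened to the mean of pixels within 100 HU of the soft-tissue
  median (an operational stand-in for "soft tissue unaffected by
  artifact"); air (< -500 HU) becomes zero attenuation; metal pixels take
  the flat soft-tissue value.
- *Metal re-insertion* pastes the segmented pixels of the Step-1 image
  into the final image (switchable).

## Problem sizes

The disk-phantom comparison runs on the `conventional_fast` preset
(256x256 image, 360 views, 512 detector cells — same source/detector
distances and FOV as the full preset) with 5 noise seeds per condition;
one full comparison (3 outside-metal counts x 2 pipelines x 2 methods x
5 seeds) takes about 2.5 minutes on one CPU core. Projector and FBP
property checks run at the full 512x512 / 720-view scale. The
untruncated-limit equivalence check uses a dedicated geometry whose image
grid (0.5 mm) is finer than the detector sampling at iso (0.6 mm), so
that reprojection of a reconstruction preserves the detector band; on
coarser grids the measured-vs-synthesized comparison is limited by the
image Nyquist rather than by the pipelines themselves.

## Known limitations

- The mirroring extension is a heuristic: it suppresses the bright rim
  (~97% of the edge-band error on a water disk) but leaves a small
  percent-level bias inside the FOV that both pipelines inherit.
- Global-window SSIM on a nearly uniform ROI is dominated by noise
  covariance and is reported for completeness; NMSE orderings are the
  robust comparison on synthetic data.
- The NMAR advantage over LMAR is modest on the disk phantom (smooth
  water background, narrow traces); it grows with anatomical complexity,
  which the synthetic phantoms deliberately lack.
- Arc detectors, short scans, cone beam, scatter and iterative or
  learning-based MAR are out of scope.
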