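# Methods

This note documents the models, defaults and numerical choices behind
`spectrecon`: an analytical simulation and reconstruction testbed for
PET-guided quantitative SPECT of Lu-177 radionuclide therapy, built
around the NEMA IEC body phantom.

## The emission model and its reconstructions

Projection data are modelled as independent Poisson counts

    y_i ~ Poisson( [P x]_i + s_i ),

where `x` is the activity image (kBq/ml), `P` the system matrix
(geometry x collimator-detector response x attenuation) and `s` an
additive term (scatter estimate; zero by default — the simulator does
not model scatter, and the reconstruction carries `s` only as an
input).

**OSEM / MLEM.** `EmissionModel.fit()` runs ordered-subsets EM,

    x <- x / (P_s^T 1) * P_s^T ( y_s / (P_s x + s_s) ),

with interleaved view subsets (view v belongs to subset v mod S) and
"iteration" meaning one full pass over all subsets.  Resolution
modelling (OSEM_RM) is the same update with the distance-dependent
CDRF inside `P`; OSEM "std" uses a PSF-free `P` plus a post-
reconstruction Gaussian (8 mm FWHM default).  Counts are converted to
kBq/ml by the calibration factor the simulation stores with each
sinogram.

**PET-guided kernelised EM (SPECTRE).** `SpectreModel` constrains the
image to `x = K alpha` and iterates the coefficients

    alpha <- alpha / (K^T P^T 1) * K^T P^T ( y / (P K alpha + s) ),

which reduces bit-for-bit to OSEM when `K` is the identity (`nn=1`) —
both models share one EM engine.  The hybrid kernel row for voxel f
over its NN x NN (x NN) window is

    K[f,j] ∝ k_p(v_f, v_j) * k_s(z_f, z_j),
    k_p = exp(-(v_f-v_j)^2 / (2 sigma_p^2 SD_v^2)) exp(-d_fj^2 / (2 sigma_dp^2)),
    k_s = exp(-(z_f-z_j)^2 / (2 sigma_s^2 SD_z^2)) exp(-d_fj^2 / (2 sigma_ds^2)),

with `v` the PET prior, `z` the current update image, `d_fj` the
voxel-to-voxel distance in voxel units, and rows normalised to unit
sum (default).  The five parameters and their roles:

| parameter | meaning | default |
|---|---|---|
| `sigma_p` | prior intensity weight; small values preserve prior edges | 1 |
| `sigma_s` | update-image intensity weight; small values treat noise as features | 1 |
| `sigma_dp`, `sigma_ds` | radial Gaussian distance weights (voxel units) | 5 |
| `nn` | window edge length (odd); `nn=1` disables guidance | 5 |

Three choices here were genuinely open and are worth recording:

* **Normalisation scale.**  Intensity differences are normalised by a
  population SD.  For the prior this scale is a property of the prior
  *study object*: the SD over the full 3D acquisition volume
  (128 x 128 x 128 at 4.8 mm), ~70 kBq/ml for the default phantom
  because the phantom fills only a few percent of the volume.  The
  single-slice 2D workflow inherits this value (`prior.meta["sd"]`)
  rather than recomputing it on the slice (whose own SD, ~230, would
  put the same `sigma_p` in a much weaker edge-preservation regime).
  The update-image scale is recomputed from the current estimate each
  sub-iteration.  Both can be overridden (`KernelParams.sd_prior`,
  `sd_estimate`), and the support convention is switchable
  (`intensity_norm`: whole image / mask / none).
* **Which image drives `k_s`.**  The SPECT factor is rebuilt after
  every sub-iteration from the EM coefficient image `alpha` (the
  update image), not from the smoothed `K alpha`.  Only the former
  lets noise in the update image act as kernel "features" — the
  behaviour `sigma_s` exists to control; with `K alpha` the kernel
  never sees the noise it is supposed to react to.  A config switch
  (`ReconConfig.kernel_estimate`) restores the smoothed variant, and
  `kernel_freeze_iteration` freezes the kernel after a chosen pass.
* **Row normalisation** keeps the EM fixed point correctly scaled
  (`K` maps a constant image to itself); it can be disabled for study.

Degenerate rules: a constant image has zero SD and its intensity
factor is set to 1; bins with zero predicted and zero measured counts
contribute ratio 1; a measured count over a zero prediction is floored
at 1e-12.  Voxels outside the reconstruction mask (body outline
dilated by 2 voxels) stay zero and their kernel rows are identity.

## System model

The projector is rotation-based and built from three exactly-adjoint
linear stages per view: (1) bilinear *splatting* of the image onto the
detector-aligned frame (the transpose of bilinear sampling; columns
sum to 1, so in-field mass is conserved exactly), (2) diagonal
attenuation weights from the rotated mu-map — `exp` of the cumulative
sum of mu x voxel length from each voxel to the detector, counting
half of the emitting voxel (a cumulative-sum approximation of per-ray
tracing), and (3) per-depth-row Gaussian convolution with the CDRF
followed by summation into bins.  Back-projection applies the literal
transposes in reverse order, so the adjoint dot-product identity holds
to machine precision for every flag combination; zero-padded
convolution with a symmetric kernel is self-adjoint, which is why the
blur needs no separate transpose.  In 3D the blur is applied
transaxially and axially with the same sigma (isotropic response), and
rotation/attenuation act slice-wise.

The CDRF is `FWHM(d) = sqrt((a d + b)^2 + Ri^2)`.  Defaults model a
medium-energy low-penetration parallel-hole collimator at the Lu-177
208 keV photopeak, derived from hole geometry: hole diameter 2.94 mm,
hole length 40.64 mm reduced by two lead mean-free paths to an
effective 38.9 mm, giving slope a = 2.94/38.9 ≈ 0.076, intercept
b = 2.94 mm, intrinsic resolution Ri = 3.8 mm (≈11 mm system FWHM at
10 cm).  Septal penetration tails are not modelled; real
medium-energy responses at 208 keV are somewhat wider, so these
coefficients are configuration, not physics constants.

The orbit is body-contoured: 120 views over 360 deg (3 deg steps),
128 bins of 4.8 mm, per-view radius = the body ellipse's support
extent along the view normal + 20 mm clearance, 30 s dwell per view.

## Phantom, priors and regions

The digital reference object is a parametric NEMA IEC body phantom:
elliptical torso cross-section (semi-axes 150 x 110 mm, cavity length
180 mm), six spheres (37/28/22/17/13/10 mm diameter, labels 1-6) on a
57.2 mm-radius ring in one transaxial plane, voxelised by binary
voxel-centre inclusion on a 4.8 mm cubic lattice.  Default
concentrations are 2784 kBq/ml (spheres) and 317 kBq/ml (background),
an 8.8:1 ratio; the attenuation map is uniform water-equivalent
0.136 cm^-1 at 208 keV inside the body.  The lung insert is off by
default and no CT realism is attempted.

PET priors emulate a noiseless theranostic Ga-68 PET of the same
object: spheres optionally reset to background *before* smoothing
(a PET scan of a lesion-free region shows smoothed background), then
an isotropic 7.5 mm FWHM Gaussian.  The "optimal" prior keeps all six
spheres; the "lesion-less" prior removes the 28/17/10 mm spheres so
that reconstructions face three PET-SPECT mutual and three
SPECT-unique features.  PET noise, spatially-variant PSF and
reconstruction artifacts are deliberately absent.

Evaluation regions are truth-matched: each sphere's circular ROI (2D)
or spherical VOI (3D) grows voxel-by-voxel in centre-distance order
and stops before exceeding the true cross-section/volume (count
rounded down), so a 37 mm sphere gets 46 voxels on the 2D 4.8 mm
grid and the 10 mm sphere only 3-4.  The background region is the
body mask eroded by 4 voxels with all spheres dilated by 4 voxels
excluded (~19 mm, about one system FWHM — far enough to avoid
spill-in/out and the slowly-converging edge zone).

## Count levels and noise

Expected counts scale the noise-free projection so that

    total counts = sensitivity x activity(MBq) x dwell(s) x n_views,

with 12.2 cps/MBq per-camera sensitivity; the dual-head count enters
through total scan time, not by double-counting views.  The activity
is read off the phantom itself (voxel sum x voxel volume): ~110 MBq
for the 2D central slice, giving ~4.8e6 expected counts per PN1
sinogram.  The low-noise PN1 level represents an early post-therapy
scan at the phantom's nominal concentrations; the high-noise PN2 level
multiplies expectations by 2^(-96/60) ≈ 0.33 — decay plus washout over
24 h → 120 h with a 60 h effective half-life chosen as typical for
Lu-177 peptide therapy (physical half-life 6.647 d alone would give
0.66).  Poisson noise is drawn independently per bin from a seeded
generator; PN1/PN2 share one noise-free parent and derive their
sub-seeds from one seed sequence.

Because the absolute count level of a "typical" therapy scan is a
modelling choice, absolute noise figures (background COV %, SNR) carry
that choice directly; ratio-type comparisons (COV-reduction and
bias-reduction factors, orderings across kernel settings) are the more
transferable outputs.  At these defaults OSEM_RM reaches ~12 %
background COV at 20 it/12 subsets; a patient-like count level several
times lower would roughly double it and proportionally enlarge the
guided reconstruction's relative advantage.

## Metrics

Per region: mean, max, SD (n-1 denominator; undefined for single-voxel
regions), COV % = 100 SD/mean, CRC = ((x̄/B) - 1)/((A_s/A_b) - 1),
SNR = (x̄ - B)/B_sigma, mean/max bias % = 100 (x̄ or max - A)/A, and
RMSE = sqrt(COV^2 RC^2 + (RC-1)^2) with COV as a fraction — the
noise-bias decomposition in quadrature (the radical is part of the
definition here).  RMSE is only reported for regions with >= 20 voxels
(small-sample SDs mislead), which on the 2D grid keeps the two largest
spheres.  All metrics are invariant to a joint rescale of image and
truth.

## Segmentation

The 42 % fixed-threshold rule: within a seed box around each sphere
(edge length 1.5 x diameter + 1 voxel per side, derived from the known
centres), threshold at 42 % of the box maximum and keep the
face-connected supra-threshold component containing the maximum,
clipped to the box.  Volume = voxel count x voxel volume; accuracy is
the signed % difference from truth, averaged signed (headline) and
absolute.  On the binary ground truth any threshold returns exactly
the voxelised sphere; on reconstructions, spill-out inflates the
apparent volume — which is precisely what the score measures.

## Study scales

The canonical 2D study (`study.build_study_2d`) is a single central
slice: 128 x 128 voxels, 120 views, ~18 s for a 40-iteration OSEM_RM
plus two guided reconstructions on one CPU.  The 3D study
(`study.build_study_3d`) is deliberately scaled down — 16 slices of
64 x 64, 60 views — sized so that 2D-vs-3D trend checks complete in
about a minute; full-resolution 3D runs are supported by the same code
but take correspondingly longer.

## What the simulations do and do not show

The simulator shares its forward model with the reconstruction (an
"inverse crime"): no scatter, septal penetration, dead time,
energy-window effects, motion or co-registration error, and the PET
prior is noiseless and perfectly aligned.  Passing tests therefore
demonstrate algorithmic correctness and the *relative* behaviour of
guided vs unguided reconstruction under ideal side information — not
clinical performance.  Known limitations worth repeating: absolute
noise levels depend on the chosen count calibration (above); with a
constant (uninformative) prior the windowed kernel cannot represent
sharp activity edges, so a Gibbs-like ripple floor appears around
edges and the "kernel as pure smoother" picture only holds where
Poisson noise dominates that floor; and kernel-guided backgrounds
converge more slowly than OSEM's, leaving a small deterministic
non-uniformity at matched iterations even on noise-free data.
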