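# spectrecon

PET-guided quantitative SPECT reconstruction with hybrid kernelised
expectation maximization, plus the analytical simulation and phantom
machinery needed to optimise and validate it.

## Why

SPECT imaging of therapeutic radionuclides such as Lu-177 is the basis
of radionuclide-therapy dosimetry, but its coarse spatial resolution
(10-15 mm FWHM with medium-energy collimators) causes severe partial
volume effects: activity in lesions smaller than ~2-3 system FWHM is
systematically underestimated, and iterative reconstructions with
resolution modelling trade that bias for noise.  In a theranostic
setting a high-resolution diagnostic PET scan (e.g. Ga-68) of the same
radionuclide distribution exists *before* therapy.  `spectrecon`
reconstructs the SPECT data guided by that PET image — the SPECTRE
approach — and provides everything needed to study it quantitatively:
a NEMA IEC body-phantom digital reference object, a rotation-based
projector with distance-dependent collimator response and attenuation,
Poisson-noise simulation at clinically motivated count levels,
recovery/noise metrics and fixed-threshold segmentation.

It is aimed at medical-physics researchers studying reconstruction
parameters and dosimetry pipelines on simulated ground truth.

## The algorithm

Projection data follow the Poisson emission model
`y ~ Poisson(P x + s)`.  The guided reconstruction constrains the
image to `x = K α` and runs ordered-subsets EM on the coefficients:

    α ← α / (Kᵀ Pᵀ 1) · Kᵀ Pᵀ ( y / (P K α + s) )

where the hybrid kernel combines a fixed PET-prior factor and an
iteration-dependent SPECT factor over an NN×NN window:

    K[f,j] ∝ exp(−(v_f−v_j)² / 2σ_p²SD_v²) · exp(−‖x_f−x_j‖² / 2σ_dp²)
           · exp(−(z_f−z_j)² / 2σ_s²SD_z²) · exp(−‖x_f−x_j‖² / 2σ_ds²)

with `v` the PET prior, `z` the current update image, distances in
voxel units and rows normalised to unit sum.  `nn=1` makes `K` the
identity and the fit is exactly OSEM (with resolution modelling when
the system models the collimator response).  See `docs/methods.md`
for parameter semantics, normalisation conventions and defaults.

The API follows the model/results pattern: build a model from data,
`fit()` it, inspect the result.

## Worked example

Simulate the low-noise single-slice IEC phantom study and compare
OSEM with resolution modelling against the PET-guided reconstruction:

```python
import spectrecon as sr
from spectrecon.study import build_study_2d, background_cov, mean_sphere_snr

study = build_study_2d(seed=42)          # phantom, system, priors, PN1/PN2 data
cfg = sr.ReconConfig(iterations=20, subsets=12)

osem_rm = sr.osem(study.pn1, study.system, cfg=cfg, mask=study.mask)
guided = sr.spectre(
    study.pn1, study.system, study.prior_optimal,
    params=sr.KernelParams(sigma_p=5, sigma_s=5, sigma_dp=5, sigma_ds=5, nn=5),
    cfg=cfg, mask=study.mask,
)
print(guided.summary())
```

```
Reconstruction summary
----------------------
algorithm     : SPECTRE
iterations    : 20 (x 12 subsets)
grid          : (128, 128) @ 4.8 mm
image total   : 110.437 MBq
image max     : 3339.5 kBq/ml
kernel        : sigma_p=5, sigma_s=5, sigma_dp=5, sigma_ds=5, NN=5
```

Scoring both against the known truth (`res.roi_metrics(study.rois)`)
prints, for this seed:

```
OSEM_RM:  background COV  12.5 %   mean sphere SNR  54.0   37 mm sphere CRC 0.964  mean bias -4.7 %
SPECTRE:  background COV  11.7 %   mean sphere SNR  65.1   37 mm sphere CRC 0.999  mean bias -2.7 %
```

Read: at matched iterations the PET-guided fit recovers the 37 mm
sphere essentially perfectly (CRC ≈ 1, bias −2.7 % vs −4.7 %) with a
quieter background and ~20 % higher sphere SNR; the gap widens at
higher iteration counts and noise levels, where OSEM_RM's background
noise keeps growing while the guided background stays nearly flat.

A command-line interface mirrors the library
(`spectrecon phantom | simulate | reconstruct | evaluate | segment |
sweep | run`), reading and writing STIR-style Interfile, NIfTI, YAML
configs and CSV tables.

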