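# Methods

## Model

The package implements a three-stage analysis of thin-slab tissue optics.

**Direct absorption.** For a slab of thickness *d* every photon is
transmitted, reflected or absorbed, so
μ_a(λ) = (1 − (Tt(λ) + Rt(λ))) / d. This is a single-scattering energy
balance, not a radiative-transfer inversion: scattering that returns light
to either sphere port is counted as "not absorbed", which is the intended
reading of total (not diffuse) transmittance and reflectance. No smoothing
or despiking is applied to Tt/Rt before the calculation. Negative raw
values (noise pushing Tt + Rt above 1) are clipped to zero and the affected
wavelengths recorded rather than raised, because they are an expected
artifact of measurement noise near full transmission. Units: *d* in cm,
μ_a in 1/cm (the biophotonics convention); the CLI takes thickness in mm
and converts.

**Unmixing.** The per-condition fit target is the ensemble *mean* spectrum
(sample SD with divisor n − 1 forms the quality envelope; per-sample fits
are available for dispersion studies but are not the default). The mean is
decomposed on the chromophore design matrix by ordinary least squares over
the full 200–1000 nm grid, unweighted. The solver is `numpy.linalg.lstsq`
(SVD): it agrees with the normal-equations formula b = (XᵀX)⁻¹Xᵀy whenever
the design is well conditioned — the test suite asserts this equivalence to
1e−8 together with residual orthogonality — but does not square the
condition number, which matters because chromophore UV bands overlap
strongly. Rank-deficient designs return the minimum-norm solution with a
warning instead of failing. Plain OLS can produce negative weights; they
are flagged prominently, and a non-negativity-constrained variant
(`scipy.optimize.nnls`) is available behind `nonneg=True` / `--nonneg`.

**Concentrations.** Unmixing weights are dimensionless because the library
columns are 0–1 normalized, so absolute volume fractions come from an
anchor: tissue water is fixed at 77% of volume (a rat-kidney figure adopted
for human kidney in the absence of a human measurement, applied to both
conditions because total water content is essentially unchanged by cancer
— bound water converts to mobile). The remaining 23% is shared among the
non-water chromophores proportionally to their weights; the water weight
itself never enters the denominator. This allocation is an inference
validated by exact 2-decimal agreement with all fourteen reference
concentration cells, not a closed form taken from a formula. Negative
weights are rejected here (volumes cannot be negative) with an error that
points to the constrained fit. Reporting rounds to 2 decimals;
comparisons between conditions use unrounded values, with the
increase/decrease label judged at reporting precision so sub-rounding
noise reads as "unchanged".

## Key parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| analysis grid | 200–1000 nm, 1 nm step (801 pts) | nm | measured spectral range; 1 nm is spectrometer-class resolution and keeps the normal equations well posed |
| slab thickness | 0.5 mm (0.05 cm) | mm | cryostat-sectioned sample thickness of the kidney study |
| water anchor | 77 | % volume | reported kidney water content |
| lipid zero cutoff | 620 | nm | no lipid absorption data below ~429 nm and negligible values up to 620 nm relative to hemoglobin |
| collinearity warning | cond(X) > 1e8 | — | warn-never-refuse policy; overlapping UV bands make moderate conditioning normal |
| zero-SD tolerance | 1e−9 | 1/cm | envelope check degenerates to equality where SD = 0 |
| noise_sd (generator) | 1e−3 | fraction | realistic integrating-sphere noise floor on a [0, 1] scale |
| n_samples (generator) | 10 | — | cohort size per condition in the study design |
| reflectance_fraction (generator) | 0.4 | — | arbitrary physical-looking Tt/Rt split; only the sum enters μ_a, asserted by test |

Library spectra are normalized 0–1 *before* fitting. The reference weight
scale (e.g. HbO₂ ≈ 193 for healthy kidney) is only interpretable under a
shared column scale, and the proportional concentration rule is invariant
to any common rescaling of the non-water weights, so the choice is
recorded in output metadata and configurable per component in the library
manifest.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* of the study: eight chromophores
with bands at their tissue positions (proteins ~230 nm, DNA ~260 nm, the
hemoglobin Soret band — 415 nm for HbO₂, shifted to 430 nm for Hb — with
HbO₂ Q-bands at 540/570 nm and a single Hb visible band at 555 nm, water
at 980 nm, a lipid band at 930 nm zeroed below 620 nm) plus
wavelength-decreasing exponential pigment baselines with distinct decay
constants (melanin 0.0035 /nm, lipofuscin 0.008 /nm, both anchored at
200 nm). Gaussian/exponential band widths are qualitative defaults chosen
so the design matrix is full rank, not digitizations of literature curves.
Cohorts are forward-generated by the exact slab inverse with i.i.d.
Gaussian noise added in measurement space (Tt and Rt, where instrument
noise actually arises), then clipped to [0, 1] with clip events counted.
True weight profiles default to the reference kidney weight vectors
rescaled by a common factor so that μ_a·d peaks at 0.9 (the slab model
requires μ_a·d ≤ 1; the concentration rule is invariant to the rescaling).

Passing tests therefore demonstrate that the *pipeline* is correct and
stable under realistic noise — they do not validate the slab energy-balance
model against radiative transfer, the fidelity of the band shapes to real
chromophores, or instrument systematics (stray light, sphere geometry,
wavelength-dependent response), none of which are modelled.

## Numerical choices and degenerate inputs

- Interpolation between library grids is piecewise linear: no spline
  overshoot, and non-negativity between non-negative knots is guaranteed.
  Wavelengths outside a source spectrum's support are zero-filled and
  annotated (the same convention the lipid spectrum uses below 429 nm).
- Normalization maps the extremes exactly to 0 and 1 (endpoint assignment
  after the affine map) so the normalized-flag invariant holds to 1e−12.
- Constant spectra cannot be normalized and raise a degenerate-spectrum
  error naming the component.
- A single-member ensemble gets an all-zero SD with an annotation; the
  SD-envelope check is skipped (reported as None) because the envelope is
  undefined.
- Duplicate wavelengths in input files are rejected (no silent averaging);
  rows are sorted by wavelength on read.
- In the full pipeline, negative OLS weights do not abort the run: the
  concentration table is omitted (None) and a note naming the
  non-negativity flag is recorded in the result and the run summary,
  keeping the spectral diagnostics available. Direct calls to
  `weights_to_concentrations` still raise.
- Output files carry a config hash and package version, never timestamps,
  and floats at 6 significant digits, so identical runs are byte-identical.

## Problem sizes

Tests and the recovery experiments run on the full 801-point grid with
8-component libraries, cohorts of 10 samples, 20 seeds per noise level and
noise SDs {0, 1e−3, 1e−2}; the whole suite completes in a few seconds.

## Known limitations

- The slab formula ignores path lengthening by scattering, so absolute
  μ_a values are effective, not intrinsic, coefficients; trends between
  conditions are the robust output.
- The 77% water anchor is a literature value for healthy rat kidney applied
  to both human conditions; it is configurable (`--water-fraction`), and
  all non-water concentrations scale linearly with 100 − anchor.
- The default band-model library is synthetic; analyses of real
  measurements should supply a measured/literature library via the
  manifest.
- Weights from differently normalized libraries are not comparable across
  runs; the normalization convention is recorded in the run summary for
  this reason.
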