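# chromounmix

Spectral unmixing of tissue absorption spectra into chromophore
contributions and volume concentrations, for diffuse-optics and tissue
spectroscopy work on thin ex vivo slabs (the motivating application is
discriminating healthy kidney from chromophobe renal cell carcinoma, CRCC).

## What it computes

For a thin slab of thickness *d*, light is either transmitted, reflected or
absorbed, so the broadband absorption coefficient follows directly from the
total transmittance *T*<sub>t</sub> and total reflectance *R*<sub>t</sub>
measured with an integrating sphere over 200–1000 nm:

μ<sub>a</sub>(λ) = [1 − (*T*<sub>t</sub>(λ) + *R*<sub>t</sub>(λ))] / *d*   (1/cm)

Per-sample spectra are averaged into a per-condition mean ± SD ensemble.
The mean spectrum *y* is then decomposed on a library of eight chromophore
absorption spectra (water, melanin, lipofuscin, DNA, HbO₂, Hb, proteins,
lipids; 0–1 normalized, stacked as the columns of a design matrix *X*) by
ordinary least squares:

**b** = (*X*ᵀ*X*)⁻¹*X*ᵀ**y**

computed with a stable SVD factorization rather than the literal inversion.
The weights *w*ᵢ reconstruct the spectrum as Σᵢ *w*ᵢ μ<sub>a,i</sub>(λ);
fit quality is judged by the fraction of wavelengths where the
reconstruction stays inside the ± SD envelope of the mean. Finally, because
the weights are dimensionless, they are converted to volume concentrations
by anchoring the tissue water fraction at 77% and sharing the remaining 23%
among the non-water chromophores proportionally to their weights:

c<sub>water</sub> = 77 %,  c<sub>i</sub> = *w*ᵢ / Σ<sub>j≠water</sub> *w*ⱼ × 23 %

No public slab dataset exists, so a first-class synthetic-data module
generates band-model chromophore libraries and seeded measurement cohorts
with known ground truth, against which every pipeline stage is tested.

## Worked example

Simulate a two-condition cohort (10 samples each, 0.5 mm slabs, noise SD
10⁻³ on *T*<sub>t</sub>/*R*<sub>t</sub>) and run the full pipeline:

```bash
chromounmix simulate --seed 7 --n-samples 10 --noise-sd 1e-3 --out demo/data
chromounmix fit --measurements demo/data/measurements \
                --library demo/data/library/library.yaml --out demo/analysis
head demo/analysis/healthy/concentrations.csv
```

```
# chromounmix 0.1.0
# config_hash: 15f81e599730
component,weight,concentration_pct
water,1.16388,77
melanin,0.0920204,0.1
lipofuscin,0.438204,0.49
DNA,1.17204,1.32
HbO2,15.5526,17.54
Hb,2.99939,3.38
proteins,0.14134,0.16
lipids,0.00404127,0
```

The fitted weights recover the simulated ground truth (e.g. HbO₂ 15.5526
vs true 15.5520) and the run summary reports rmse ≈ 0.0089 1/cm with 98.5%
of wavelengths inside the SD envelope. The concentration column is the
water-anchored allocation of the 23% non-water volume. Converting measured
weight vectors directly (weights-only mode):

```bash
chromounmix concentrations --weights weights.csv --water-fraction 77 --out conc.csv
```

Library functions mirror the CLI: `compute_mua`, `ensemble_stats`,
`solve_weights`, `reconstruct`, `check_within_sd`, `fit_condition`,
`weights_to_concentrations`, `compare_conditions`,
`make_default_library`, `generate_cohort`.

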