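"""Parametric chromophore libraries and simulated measurement cohorts.

No public dataset of kidney slab spectra exists, so every pipeline stage is
exercised against synthetic data with known ground truth.  The default
library places each chromophore's characteristic bands where they sit in
tissue spectra — proteins ~230 nm, DNA ~260 nm, the hemoglobin Soret band
~415 nm with Q-bands at 540/570 nm, water at 980 nm, a lipid band in the NIR
— and gives the pigments (melanin, lipofuscin) the wavelength-decreasing
broadband absorption that forms the UV-visible baseline.  Band widths and
decay constants are package defaults chosen for qualitative resemblance to
published curves, not quantitative fidelity; all are configurable and
recorded in the ground-truth output.

Cohorts are forward-generated by the exact slab inverse (Tt + Rt =
1 - mu_a*d) with additive Gaussian noise applied in measurement space (Tt
and Rt, where real instrument noise arises), then clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .direct_mua import AbsorptionSpectrum, SampleMeasurement, forward_ttrt
from .spectral_library import (
    CANONICAL_ORDER,
    ComponentSpectrum,
    LIPID_ZERO_CUTOFF_NM,
    SpectralLibrary,
    WavelengthGrid,
    apply_zero_convention,
    normalize_unit_range,
)
from .unmixing import WeightVector

__all__ = [
    "BandModel",
    "SyntheticScenario",
    "GroundTruth",
    "evaluate_band",
    "make_default_library",
    "default_band_models",
    "generate_cohort",
    "scale_weights_physical",
]

#: Exponential decays are anchored at the grid start of the analysis range:
#: value = amplitude * exp(-k * (lambda - 200 nm)).
DECAY_ANCHOR_NM = 200.0


@dataclass(frozen=True)
class BandModel:
    """One absorption band: a Gaussian peak or an exponential decay.

    gaussian:           amplitude * exp(-(lambda - center)^2 / (2 width^2))
    exponential-decay:  amplitude * exp(-decay * (lambda - 200 nm))
    """

    kind: str
    amplitude: float = 1.0
    center_nm: float | None = None
    width_nm: float | None = None
    decay_per_nm: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "exponential-decay"):
            raise ValueError(f"unknown band kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.kind == "gaussian":
            if self.center_nm is None or self.width_nm is None:
                raise ValueError("gaussian band needs center_nm and width_nm")
            if not self.width_nm > 0:
                raise ValueError("width_nm must be > 0")
        else:
            if self.decay_per_nm is None or not self.decay_per_nm > 0:
                raise ValueError("exponential decay needs decay_per_nm > 0")


def evaluate_band(model: BandModel, grid: WavelengthGrid) -> np.ndarray:
    """Evaluate one band model on a wavelength grid."""
    wl = grid.values
    if model.kind == "gaussian":
        z = (wl - model.center_nm) / model.width_nm
        return model.amplitude * np.exp(-0.5 * z**2)
    return model.amplitude * np.exp(-model.decay_per_nm * (wl - DECAY_ANCHOR_NM))


def default_band_models() -> dict[str, list[BandModel]]:
    """Band parameters of the default eight-chromophore library.

    Widths and decay constants are qualitative defaults; the two pigments
    get distinct decay constants (and melanin a slower tail) so the design
    matrix stays full rank, and Hb's visible band sits at 555 nm to separate
    it from the HbO2 Q-band doublet at 540/570 nm.
    """
    return {
        "water": [BandModel("gaussian", 1.0, center_nm=980.0, width_nm=40.0)],
        "melanin": [BandModel("exponential-decay", 1.0, decay_per_nm=0.0035)],
        "lipofuscin": [BandModel("exponential-decay", 1.0, decay_per_nm=0.008)],
        "DNA": [BandModel("gaussian", 1.0, center_nm=260.0, width_nm=15.0)],
        "HbO2": [
            BandModel("gaussian", 1.0, center_nm=415.0, width_nm=18.0),
            BandModel("gaussian", 0.25, center_nm=540.0, width_nm=14.0),
            BandModel("gaussian", 0.25, center_nm=570.0, width_nm=14.0),
        ],
        "Hb": [
            BandModel("gaussian", 1.0, center_nm=430.0, width_nm=20.0),
            BandModel("gaussian", 0.3, center_nm=555.0, width_nm=18.0),
        ],
        "proteins": [BandModel("gaussian", 1.0, center_nm=230.0, width_nm=12.0)],
        "lipids": [BandModel("gaussian", 1.0, center_nm=930.0, width_nm=30.0)],
    }


def make_default_library(
    grid: WavelengthGrid | None = None,
    band_models: dict[str, list[BandModel]] | None = None,
) -> SpectralLibrary:
    """Build the default eight-component library, normalized 0-1.

    Components come in the canonical analysis order (water, melanin,
    lipofuscin, DNA, HbO2, Hb, proteins, lipids).  Lipids are zeroed below
    620 nm per the lipid zero-absorption convention.  The grid must cover
    200-1000 nm so every band center is inside it.
    """
    if grid is None:
        grid = WavelengthGrid.default()
    models = band_models if band_models is not None else default_band_models()
    lo, hi = grid.span
    if lo > 200.0 or hi < 1000.0:
        raise ValueError(
            f"grid [{lo:g}, {hi:g}] nm does not cover the 200-1000 nm band set"
        )
    components = []
    for name in CANONICAL_ORDER:
        values = np.zeros(len(grid))
        for band in models[name]:
            values = values + evaluate_band(band, grid)
        spec = ComponentSpectrum(
            name=name, grid=grid, values=values, provenance="synthetic band model"
        )
        if name == "lipids":
            spec = apply_zero_convention(spec, LIPID_ZERO_CUTOFF_NM)
        components.append(normalize_unit_range(spec))
    return SpectralLibrary(components=components)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one simulated measurement cohort.

    Mirrors the real study design: 0.5 mm slabs (0.05 cm), 10 samples per
    condition, additive Gaussian noise on Tt and Rt.  ``noise_sd`` default
    1e-3 is a realistic integrating-sphere noise floor on a [0, 1]
    transmittance scale.
    """

    seed: int
    true_weights: WeightVector
    n_samples: int = 10
    thickness_cm: float = 0.05
    noise_sd: float = 1e-3
    reflectance_fraction: float = 0.4
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: true weights, true mu_a, clipping counts."""

    scenario: SyntheticScenario
    true_mua: AbsorptionSpectrum
    clip_events: int


def scale_weights_physical(
    weights: WeightVector,
    library: SpectralLibrary,
    thickness_cm: float = 0.05,
    margin: float = 0.9,
) -> WeightVector:
    """Rescale weights so the implied mu_a * d peaks at ``margin`` (< 1).

    The slab model requires mu_a * d <= 1; weight vectors quoted on other
    scales are brought into the physical regime by a common factor, which
    the proportional concentration rule is invariant to.
    """
    X = np.column_stack([c.values for c in library.components])
    peak = float((X @ weights.weights).max()) * thickness_cm
    if peak <= 0:
        raise ValueError("weights imply a non-positive absorption peak")
    return WeightVector(
        component_names=weights.component_names,
        weights=weights.weights * (margin / peak),
    )


def generate_cohort(
    scenario: SyntheticScenario, library: SpectralLibrary
) -> tuple[list[SampleMeasurement], GroundTruth]:
    """Forward-simulate a cohort of slab measurements with known truth.

    mu_a = X @ true_weights; each sample's Tt/Rt come from the exact slab
    inverse plus independent seeded Gaussian noise, clipped to [0, 1].
    Clipping events are counted so tests can bound the distortion they
    introduce.  Deterministic under a fixed seed.
    """
    if tuple(library.names) != scenario.true_weights.component_names:
        raise ValueError("true_weights order does not match library order")
    X = np.column_stack([c.values for c in library.components])
    mua_values = X @ scenario.true_weights.weights
    if mua_values.min() < 0:
        raise ValueError("true weights imply negative absorption")
    true_mua = AbsorptionSpectrum(grid=library.grid, mua=mua_values)
    attenuation = mua_values * scenario.thickness_cm
    if attenuation.max() > 1.0:
        wl = library.grid.values[int(np.argmax(attenuation))]
        raise ValueError(
            f"mu_a * d = {attenuation.max():.4g} > 1 at {wl:g} nm; "
            "rescale the true weights (see scale_weights_physical)"
        )
    clean = forward_ttrt(
        true_mua,
        scenario.thickness_cm,
        scenario.reflectance_fraction,
        condition=scenario.condition,
    )
    rng = np.random.default_rng(scenario.seed)
    samples = []
    clip_events = 0
    for i in range(scenario.n_samples):
        noise = rng.normal(0.0, scenario.noise_sd, size=(2, len(library.grid)))
        Tt = clean.Tt + noise[0] if scenario.noise_sd > 0 else clean.Tt.copy()
        Rt = clean.Rt + noise[1] if scenario.noise_sd > 0 else clean.Rt.copy()
        clip_events += int(((Tt < 0) | (Tt > 1) | (Rt < 0) | (Rt > 1)).sum())
        samples.append(
            SampleMeasurement(
                sample_id=f"{scenario.condition}_{i:02d}",
                condition=scenario.condition,
                grid=library.grid,
                Tt=np.clip(Tt, 0.0, 1.0),
                Rt=np.clip(Rt, 0.0, 1.0),
                thickness_cm=scenario.thickness_cm,
            )
        )
    return samples, GroundTruth(
        scenario=scenario, true_mua=true_mua, clip_events=clip_events
    )
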