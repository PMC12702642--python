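"""Reference weight vectors for kidney tissue.

Chromophore weights reported for healthy and chromophobe renal cell
carcinoma (CRCC) human kidney, obtained by least-squares unmixing of mean
absorption spectra measured on 0.5 mm slabs from 10 patients.  They serve
two roles here: as the weights-only input to the water-anchored
concentration conversion, and as realistic ground-truth weight profiles for
the synthetic cohort generator (after rescaling into the physical
mu_a * d <= 1 regime).
"""

from __future__ import annotations

from .spectral_library import CANONICAL_ORDER
from .unmixing import WeightVector

__all__ = [
    "KIDNEY_WEIGHTS_HEALTHY",
    "KIDNEY_WEIGHTS_CRCC",
    "KIDNEY_WATER_FRACTION_PCT",
]

#: Water volume fraction of kidney tissue (%), the anchor of the
#: concentration conversion.  Measured for rat kidney; adopted for human
#: tissue in the absence of a human figure, for both conditions (total
#: water content is unchanged by cancer; bound water converts to mobile).
KIDNEY_WATER_FRACTION_PCT = 77.0

KIDNEY_WEIGHTS_HEALTHY = WeightVector(
    component_names=CANONICAL_ORDER,
    weights=[14.47, 1.00, 5.65, 14.55, 193.21, 37.28, 1.71, 0.07],
)

KIDNEY_WEIGHTS_CRCC = WeightVector(
    component_names=CANONICAL_ORDER,
    weights=[18.46, 0.1, 8.97, 30.91, 254.04, 11.05, 5.22, 0.43],
)
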