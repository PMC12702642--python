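"""Weight-to-concentration conversion anchored on tissue water content.

The unmixing weights are dimensionless (the component spectra are normalized
0-1 before fitting), so absolute volume fractions cannot be read off them
directly.  Instead the tissue water volume fraction is anchored at a known
value (77% for kidney, a rat-kidney figure adopted for human tissue in the
absence of human data) and the remaining volume is shared among the other
chromophores proportionally to their fitted weights:

    c_water = f_water
    c_i     = w_i / sum_{j != water} w_j * (100 - f_water)     [% volume]

The water weight itself never enters the allocation denominator: water is
anchored, not allocated.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DEFAULT_WATER_FRACTION_PCT",
    "NegativeWeightError",
    "ConcentrationTable",
    "weights_to_concentrations",
    "compare_conditions",
]

DEFAULT_WATER_FRACTION_PCT = 77.0
WATER_NAME = "water"


class NegativeWeightError(ValueError):
    """Raised when a negative non-water weight reaches the converter."""


@dataclass(frozen=True)
class ConcentrationTable:
    """Per-component volume concentrations in % of tissue volume.

    ``entries`` maps component name to its unrounded concentration;
    ``rounding`` is the decimal precision used for reporting (2, the
    convention of the published table).  Entries sum to 100% exactly
    (pre-rounding) and the water entry equals the anchor.
    """

    condition: str
    entries: dict[str, float]
    water_fraction_pct: float = DEFAULT_WATER_FRACTION_PCT
    rounding: int = 2

    def rounded(self) -> dict[str, float]:
        return {k: round(v, self.rounding) for k, v in self.entries.items()}

    def __getitem__(self, component: str) -> float:
        return self.entries[component]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": list(self.entries),
                "concentration_pct": list(self.entries.values()),
            }
        )


def _water_key(names) -> str:
    for name in names:
        if name.lower() == WATER_NAME:
            return name
    raise ValueError(
        "weight vector has no 'water' component; the conversion is anchored "
        "on the tissue water fraction and cannot run without it"
    )


def weights_to_concentrations(
    weights,
    water_fraction_pct: float = DEFAULT_WATER_FRACTION_PCT,
    condition: str = "",
    rounding: int = 2,
) -> ConcentrationTable:
    """Convert unmixing weights to volume concentrations (% of tissue).

    Parameters
    ----------
    weights
        A :class:`~chromounmix.unmixing.WeightVector` or any mapping of
        component name to weight.  Must include a ``water`` entry; all
        non-water weights must be non-negative.
    water_fraction_pct
        The anchored tissue water volume fraction, in percent (default 77).

    Raises
    ------
    NegativeWeightError
        If any non-water weight is negative.  Concentrations are volumes;
        rerun the fit with the non-negativity constraint (``nonneg=True`` /
        ``--nonneg``) if ordinary least squares produced negative weights.
    """
    if not 0.0 < water_fraction_pct <= 100.0:
        raise ValueError("water_fraction_pct must be in (0, 100]")
    mapping = dict(weights.items() if hasattr(weights, "items") else weights)
    water = _water_key(mapping)
    others = {k: float(v) for k, v in mapping.items() if k != water}
    negative = sorted(k for k, v in others.items() if v < 0)
    if negative:
        raise NegativeWeightError(
            f"negative weights for {negative}: concentrations are volume "
            "fractions and cannot be negative; refit with the "
            "non-negativity constraint (nonneg=True / --nonneg)"
        )
    remainder = 100.0 - water_fraction_pct
    total = sum(others.values())
    entries: dict[str, float] = {}
    if remainder == 0.0:
        entries = {k: 0.0 for k in others}
    else:
        if total == 0.0:
            raise ValueError(
                "all non-water weights are zero: cannot allocate the "
                f"{remainder:g}% non-water volume"
            )
        entries = {k: v / total * remainder for k, v in others.items()}
    # preserve input component order, water included at its own position
    out: dict[str, float] = {}
    for name in mapping:
        out[name] = water_fraction_pct if name == water else entries[name]
    return ConcentrationTable(
        condition=condition,
        entries=out,
        water_fraction_pct=water_fraction_pct,
        rounding=rounding,
    )


def compare_conditions(a: ConcentrationTable, b: ConcentrationTable) -> pd.DataFrame:
    """Signed per-component concentration differences between two conditions.

    Returns a frame with columns ``component``, ``concentration_a``,
    ``concentration_b``, ``delta`` (b - a, unrounded) and ``direction``
    (increased / decreased / unchanged).  Direction is judged at the tables'
    reporting precision so that sub-rounding noise reads as "unchanged",
    while ``delta`` stays unrounded.
    """
    if set(a.entries) != set(b.entries):
        only_a = sorted(set(a.entries) - set(b.entries))
        only_b = sorted(set(b.entries) - set(a.entries))
        raise ValueError(
            f"component sets differ (only in first: {only_a}, "
            f"only in second: {only_b})"
        )
    nd = min(a.rounding, b.rounding)
    rows = []
    for name in a.entries:
        ca, cb = a.entries[name], b.entries[name]
        if round(cb, nd) == round(ca, nd):
            direction = "unchanged"
        else:
            direction = "increased" if cb > ca else "decreased"
        rows.append(
            {
                "component": name,
                "concentration_a": ca,
                "concentration_b": cb,
                "delta": cb - ca,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)
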