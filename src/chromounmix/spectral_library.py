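"""Chromophore absorption-spectrum library.

A tissue absorption spectrum is modelled as a weighted sum of the absorption
spectra of its chromophores (water, melanin, lipofuscin, DNA, oxygenated and
deoxygenated hemoglobin, proteins, lipids).  This module holds the component
spectra on a shared wavelength grid, normalizes them to a common 0-1 scale,
resamples heterogeneous literature grids onto the analysis grid, applies the
lipid zero-absorption convention below 620 nm, and assembles the design
matrix X (one column per chromophore, one row per wavelength) consumed by the
least-squares unmixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CANONICAL_ORDER",
    "DEFAULT_GRID_NM",
    "COLLINEARITY_COND_THRESHOLD",
    "DegenerateSpectrumError",
    "GridMismatchError",
    "CollinearityWarning",
    "WavelengthGrid",
    "ComponentSpectrum",
    "SpectralLibrary",
    "DesignMatrix",
    "normalize_unit_range",
    "resample_to_grid",
    "apply_zero_convention",
    "build_design_matrix",
]

#: Component order used throughout the kidney analysis (water first, then the
#: pigments, nucleic acids, the two hemoglobin forms, proteins and lipids).
CANONICAL_ORDER = (
    "water",
    "melanin",
    "lipofuscin",
    "DNA",
    "HbO2",
    "Hb",
    "proteins",
    "lipids",
)

#: Analysis grid: 200-1000 nm at 1 nm steps (801 points).  The measured
#: spectral range is 200-1000 nm; 1 nm matches spectrometer-class resolution.
DEFAULT_GRID_NM = (200.0, 1000.0, 1.0)

#: Design matrices with a 2-norm condition number above this are flagged as
#: numerically collinear (warn, never refuse to solve).
COLLINEARITY_COND_THRESHOLD = 1e8

#: Default cutoff for the lipid zero-absorption convention (no lipid
#: absorption data below ~429 nm; negligible up to 620 nm).
LIPID_ZERO_CUTOFF_NM = 620.0


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum cannot be normalized (max equals min)."""


class GridMismatchError(ValueError):
    """Raised when spectra expected to share a wavelength grid do not."""


class CollinearityWarning(UserWarning):
    """Emitted when design-matrix columns are numerically collinear."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths in nm.

    Parameters
    ----------
    values
        Wavelengths in nanometres, strictly increasing, finite, within the
        100-3000 nm sanity range.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("wavelength grid contains non-finite values")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if values[0] < 100.0 or values[-1] > 3000.0:
            raise ValueError(
                "wavelengths outside the 100-3000 nm sanity range: "
                f"[{values[0]:g}, {values[-1]:g}]"
            )
        object.__setattr__(self, "values", values)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """The 200-1000 nm, 1 nm step analysis grid (801 points)."""
        lo, hi, step = DEFAULT_GRID_NM
        n = int(round((hi - lo) / step)) + 1
        return cls(np.linspace(lo, hi, n))

    def __len__(self) -> int:
        return len(self.values)

    def matches(self, other: "WavelengthGrid") -> bool:
        return len(self) == len(other) and bool(
            np.array_equal(self.values, other.values)
        )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


@dataclass(frozen=True)
class ComponentSpectrum:
    """One chromophore's absorption curve on a wavelength grid.

    ``values`` are dimensionless after 0-1 normalization, or absolute
    absorption coefficients in 1/cm before it; ``normalized`` records which.
    ``extrapolated`` marks wavelengths that were zero-filled outside the
    source data's support during resampling.
    """

    name: str
    grid: WavelengthGrid
    values: np.ndarray
    normalized: bool = False
    provenance: str = ""
    extrapolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.grid),):
            raise ValueError(
                f"component {self.name!r}: {values.size} values for a "
                f"{len(self.grid)}-point grid"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"component {self.name!r}: non-finite values")
        if np.any(values < 0):
            raise ValueError(f"component {self.name!r}: negative absorption")
        if self.normalized:
            if abs(values.min()) > 1e-12 or abs(values.max() - 1.0) > 1e-12:
                raise ValueError(
                    f"component {self.name!r} flagged normalized but spans "
                    f"[{values.min():g}, {values.max():g}]"
                )
        object.__setattr__(self, "values", values)
        if self.extrapolated is not None:
            mask = np.asarray(self.extrapolated, dtype=bool)
            if mask.shape != values.shape:
                raise ValueError("extrapolation mask length mismatch")
            object.__setattr__(self, "extrapolated", mask)


def normalize_unit_range(spectrum: ComponentSpectrum) -> ComponentSpectrum:
    """Rescale a spectrum affinely so min(values) = 0 and max(values) = 1.

    Idempotent and rank-order preserving.  Raises
    :class:`DegenerateSpectrumError` for a constant spectrum.
    """
    v = spectrum.values
    if v.size < 2:
        raise ValueError(f"component {spectrum.name!r}: need >= 2 points")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        raise DegenerateSpectrumError(
            f"component {spectrum.name!r} is constant (value {vmin:g}); "
            "cannot normalize to unit range"
        )
    scaled = (v - vmin) / (vmax - vmin)
    # enforce exact endpoint values despite rounding
    scaled[v == vmin] = 0.0
    scaled[v == vmax] = 1.0
    return replace(spectrum, values=scaled, normalized=True)


def resample_to_grid(
    spectrum: ComponentSpectrum, target: WavelengthGrid
) -> ComponentSpectrum:
    """Piecewise-linear resampling onto ``target``.

    Target wavelengths outside the source support are zero-filled and marked
    in the output's ``extrapolated`` annotation.  Linear interpolation between
    non-negative knots cannot go negative or overshoot, which is why no
    spline is used.
    """
    if len(spectrum.grid) < 2:
        raise ValueError(f"component {spectrum.name!r}: need >= 2 knots")
    src_wl = spectrum.grid.values
    out = np.interp(target.values, src_wl, spectrum.values, left=0.0, right=0.0)
    outside = (target.values < src_wl[0]) | (target.values > src_wl[-1])
    out[outside] = 0.0
    return ComponentSpectrum(
        name=spectrum.name,
        grid=target,
        values=out,
        normalized=False,
        provenance=spectrum.provenance,
        extrapolated=outside,
    )


def apply_zero_convention(
    spectrum: ComponentSpectrum, cutoff_nm: float
) -> ComponentSpectrum:
    """Zero out absorption below ``cutoff_nm`` (lipid convention: 620 nm).

    Lipid absorption data do not exist below ~429 nm and are negligible
    relative to hemoglobin up to 620 nm, so lipid spectra are conventionally
    set to exactly zero there.  Water is left as provided: its visible
    absorption is genuinely small but nonzero.  A no-op when the cutoff lies
    below the grid start.
    """
    mask = spectrum.grid.values < cutoff_nm
    if not mask.any():
        return spectrum
    values = spectrum.values.copy()
    values[mask] = 0.0
    normalized = spectrum.normalized and values.max() == 1.0 and values.min() == 0.0
    return replace(spectrum, values=values, normalized=normalized)


@dataclass
class SpectralLibrary:
    """Ordered chromophore spectra on one shared grid.

    The order of ``components`` fixes the design-matrix column order and
    hence the order of the unmixing weight vector.
    """

    components: list[ComponentSpectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("library must contain at least one component")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate component names: {dupes}")
        grid = self.components[0].grid
        bad = [c.name for c in self.components[1:] if not c.grid.matches(grid)]
        if bad:
            raise GridMismatchError(
                f"components not on the shared grid: {bad}"
            )

    @property
    def grid(self) -> WavelengthGrid:
        return self.components[0].grid

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def __len__(self) -> int:
        return len(self.components)

    def __getitem__(self, name: str) -> ComponentSpectrum:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class DesignMatrix:
    """The unmixing design matrix X plus the metadata needed to read it.

    ``matrix`` has one row per wavelength and one column per component, in
    library order.  ``condition_number`` is the 2-norm condition diagnostic;
    ``collinear`` records whether it exceeded the warning threshold.
    """

    matrix: np.ndarray
    component_names: tuple[str, ...]
    grid: WavelengthGrid
    condition_number: float
    collinear: bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def build_design_matrix(library: SpectralLibrary) -> DesignMatrix:
    """Stack the library spectra into the (n_wavelengths, n_components) X.

    Always computes the condition number; emits :class:`CollinearityWarning`
    (and records it) when columns are numerically collinear, but never
    refuses to build.
    """
    X = np.column_stack([c.values for c in library.components])
    cond = float(np.linalg.cond(X))
    collinear = not np.isfinite(cond) or cond > COLLINEARITY_COND_THRESHOLD
    if collinear:
        warnings.warn(
            f"design matrix is numerically collinear (cond = {cond:.3g}); "
            "weights may be unstable",
            CollinearityWarning,
            stacklevel=2,
        )
    return DesignMatrix(
        matrix=X,
        component_names=tuple(library.names),
        grid=library.grid,
        condition_number=cond,
        collinear=collinear,
    )
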