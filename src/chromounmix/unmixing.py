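"""Least-squares spectral unmixing and fit-quality assessment.

The mean experimental absorption spectrum y is decomposed on the library
design matrix X by ordinary least squares, b = argmin ||y - X b||^2 — the
solution of the normal equations b = (X^T X)^{-1} X^T y, computed here by a
stable SVD-based solver.  The fitted weights reconstruct the spectrum as
sum_i w_i * mu_ai(lambda), and fit quality is judged against the per-
wavelength SD envelope of the measured ensemble: a good reconstruction stays
within one SD of the mean everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .concentrations import (
    ConcentrationTable,
    DEFAULT_WATER_FRACTION_PCT,
    NegativeWeightError,
    weights_to_concentrations,
)
from .direct_mua import (
    AbsorptionEnsemble,
    AbsorptionSpectrum,
    SampleMeasurement,
    compute_mua,
    ensemble_stats,
)
from .spectral_library import DesignMatrix, SpectralLibrary, build_design_matrix

__all__ = [
    "WeightVector",
    "UnmixingResult",
    "ConditionFit",
    "RankDeficiencyWarning",
    "NegativeWeightWarning",
    "solve_weights",
    "reconstruct",
    "check_within_sd",
    "fit_condition",
]

#: Zero-SD wavelengths require the reconstruction to match the mean to this
#: absolute tolerance to count as "within the envelope".
ZERO_SD_TOL = 1e-9


class RankDeficiencyWarning(UserWarning):
    """Design matrix is rank deficient; minimum-norm weights returned."""


class NegativeWeightWarning(UserWarning):
    """Ordinary least squares produced negative weights."""


@dataclass(frozen=True)
class WeightVector:
    """Fitted component weights, in library (design-matrix column) order."""

    component_names: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.component_names),):
            raise ValueError(
                f"{w.size} weights for {len(self.component_names)} components"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite values")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "component_names", tuple(self.component_names))

    def items(self):
        return zip(self.component_names, self.weights.tolist())

    def __getitem__(self, name: str) -> float:
        try:
            i = self.component_names.index(name)
        except ValueError:
            raise KeyError(name) from None
        return float(self.weights[i])

    @property
    def has_negative(self) -> bool:
        return bool((self.weights < 0).any())


@dataclass(frozen=True)
class UnmixingResult:
    """Weights, reconstruction and residual diagnostics for one fit.

    ``raw_reconstruction`` is the signed weighted sum (negative values
    possible with negative weights); ``reconstruction`` is its clipped-at-
    zero export as an absorption spectrum.  ``within_sd_fraction`` is None
    when the ensemble SD envelope is undefined (single-member ensemble).
    """

    weights: WeightVector
    reconstruction: AbsorptionSpectrum
    raw_reconstruction: np.ndarray
    residuals: np.ndarray
    rmse: float
    within_sd_fraction: float | None
    within_sd_mask: np.ndarray | None
    condition_number: float


def solve_weights(
    X: DesignMatrix | np.ndarray,
    y: np.ndarray,
    component_names: tuple[str, ...] | None = None,
    nonneg: bool = False,
) -> WeightVector:
    """Least-squares minimizer of ||y - X b||^2.

    Uses a stable SVD factorization rather than literally inverting X^T X:
    the two agree whenever X is well conditioned, but the normal equations
    square the condition number and the UV bands of a chromophore library
    overlap strongly.  Rank-deficient designs yield the minimum-norm
    solution with a :class:`RankDeficiencyWarning`.  With ``nonneg=True``
    the weights are constrained to be non-negative (NNLS).
    """
    if isinstance(X, DesignMatrix):
        names = X.component_names
        matrix = X.matrix
    else:
        matrix = np.asarray(X, dtype=float)
        if matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        names = component_names or tuple(
            f"component_{i}" for i in range(matrix.shape[1])
        )
    y = np.asarray(y, dtype=float)
    if y.shape != (matrix.shape[0],):
        raise ValueError(
            f"y has length {y.size}, design matrix has {matrix.shape[0]} rows"
        )
    if len(names) != matrix.shape[1]:
        raise ValueError("component_names length does not match column count")
    if nonneg:
        w, _ = scipy.optimize.nnls(matrix, y)
    else:
        w, _, rank, _ = np.linalg.lstsq(matrix, y, rcond=None)
        if rank < matrix.shape[1]:
            warnings.warn(
                f"design matrix rank {rank} < {matrix.shape[1]} columns; "
                "returning the minimum-norm solution",
                RankDeficiencyWarning,
                stacklevel=2,
            )
        if (w < 0).any():
            neg = [n for n, v in zip(names, w) if v < 0]
            warnings.warn(
                f"ordinary least squares produced negative weights for {neg}; "
                "consider the non-negativity constraint (nonneg=True)",
                NegativeWeightWarning,
                stacklevel=2,
            )
    return WeightVector(component_names=tuple(names), weights=w)


def reconstruct(
    library: SpectralLibrary, weights: WeightVector
) -> tuple[AbsorptionSpectrum, np.ndarray]:
    """Weighted sum of the library spectra: sum_i w_i * mu_ai(lambda).

    Returns the exported absorption spectrum (negative sums clipped to zero
    and annotated) together with the raw signed reconstruction used for
    residual diagnostics.
    """
    if tuple(library.names) != weights.component_names:
        raise ValueError(
            f"weight order {weights.component_names} does not match "
            f"library order {tuple(library.names)}"
        )
    X = np.column_stack([c.values for c in library.components])
    raw = X @ weights.weights
    clipped = raw < 0
    spectrum = AbsorptionSpectrum(
        grid=library.grid, mua=np.where(clipped, 0.0, raw), clipped=clipped
    )
    return spectrum, raw


def check_within_sd(
    observed: AbsorptionEnsemble, reconstruction: AbsorptionSpectrum
) -> tuple[float, np.ndarray]:
    """Fraction of wavelengths where |mean - reconstruction| <= SD.

    The published fit-quality criterion: the reconstructed spectrum should
    lie inside the +/- SD envelope of the mean experimental spectrum.  At
    zero-SD wavelengths the envelope degenerates to a point, so exact
    equality (tolerance 1e-9) is required there.  Returns the fraction and
    the per-wavelength boolean mask.
    """
    if len(observed) < 2:
        raise ValueError(
            "SD envelope undefined for a single-member ensemble; "
            "need >= 2 members"
        )
    if not observed.grid.matches(reconstruction.grid):
        raise ValueError("ensemble and reconstruction are on different grids")
    deviation = np.abs(observed.mean.mua - reconstruction.mua)
    mask = np.where(
        observed.sd > 0, deviation <= observed.sd, deviation <= ZERO_SD_TOL
    )
    return float(mask.mean()), mask


@dataclass(frozen=True)
class ConditionFit:
    """Complete per-condition pipeline output.

    Bundles the measured ensemble, the unmixing result and the derived
    concentration table.  ``concentrations`` is None when plain OLS produced
    negative weights (volume fractions cannot be negative); the
    ``concentration_note`` then names the non-negativity flag to use.
    """

    condition: str
    ensemble: AbsorptionEnsemble
    unmixing: UnmixingResult
    concentrations: ConcentrationTable | None
    concentration_note: str = ""


def fit_condition(
    condition_measurements: list[SampleMeasurement],
    library: SpectralLibrary,
    water_fraction_pct: float = DEFAULT_WATER_FRACTION_PCT,
    nonneg: bool = False,
    condition: str | None = None,
) -> ConditionFit:
    """Run the full per-condition pipeline.

    Composes: direct mu_a calculation per sample -> ensemble mean/SD ->
    least-squares weights on the ensemble mean -> reconstruction ->
    SD-envelope check -> water-anchored concentrations.  The fit target is
    the ensemble mean spectrum, not the individual samples.
    """
    if not condition_measurements:
        raise ValueError("fit stage 'input': no measurements supplied")
    if condition is None:
        condition = condition_measurements[0].condition
    try:
        members = [compute_mua(m) for m in condition_measurements]
    except Exception as exc:
        raise RuntimeError(f"fit stage 'compute_mua': {exc}") from exc
    try:
        ensemble = ensemble_stats(members, condition)
    except Exception as exc:
        raise RuntimeError(f"fit stage 'ensemble_stats': {exc}") from exc
    try:
        design = build_design_matrix(library)
        if not design.grid.matches(ensemble.grid):
            raise ValueError("library grid does not match measurement grid")
        weights = solve_weights(design, ensemble.mean.mua, nonneg=nonneg)
    except Exception as exc:
        raise RuntimeError(f"fit stage 'solve_weights': {exc}") from exc
    try:
        spectrum, raw = reconstruct(library, weights)
    except Exception as exc:
        raise RuntimeError(f"fit stage 'reconstruct': {exc}") from exc
    residuals = ensemble.mean.mua - raw
    rmse = float(np.sqrt(np.mean(residuals**2)))
    if ensemble.single_member:
        fraction, mask = None, None
    else:
        fraction, mask = check_within_sd(ensemble, spectrum)
    note = ""
    try:
        table = weights_to_concentrations(
            weights, water_fraction_pct=water_fraction_pct, condition=condition
        )
    except NegativeWeightError as exc:
        table = None
        note = str(exc)
        warnings.warn(
            f"condition {condition!r}: {note}", NegativeWeightWarning, stacklevel=2
        )
    result = UnmixingResult(
        weights=weights,
        reconstruction=spectrum,
        raw_reconstruction=raw,
        residuals=residuals,
        rmse=rmse,
        within_sd_fraction=fraction,
        within_sd_mask=mask,
        condition_number=design.condition_number,
    )
    return ConditionFit(
        condition=condition,
        ensemble=ensemble,
        unmixing=result,
        concentrations=table,
        concentration_note=note,
    )
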